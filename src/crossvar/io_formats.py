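"""Tabular file formats: linkage maps, genotypes, phenotypes, effects, crosses.

All files are tab-separated UTF-8 with a header row; ``NA`` is the missing
sentinel on write, ``NA`` and ``.`` are accepted on read.  Floats are written
with 12 significant digits so write/read round-trips are value-identical for
practical purposes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    CrossPrediction,
    FormatError,
    GenotypeMatrix,
    LinkageMap,
    MarkerEffects,
    MatingScheme,
    PhenotypeTable,
)

__all__ = [
    "read_linkage_map",
    "write_linkage_map",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_effects",
    "write_effects",
    "read_cross_predictions",
    "write_cross_predictions",
    "load_config",
]

logger = logging.getLogger(__name__)

_NA_VALUES = ["NA", "."]
_FLOAT_FMT = "%.12g"
INTERCEPT_ROW = "__intercept__"


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep="\t", dtype=str, na_values=_NA_VALUES, keep_default_na=False, **kw
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_linkage_map(path) -> LinkageMap:
    """Read a map TSV with columns ``marker``, ``chrom``, ``pos_cM``.

    Rows are re-sorted by position within each chromosome; the load order of
    chromosomes is preserved.
    """
    t = _read_tsv(path)
    required = ["marker", "chrom", "pos_cM"]
    if list(t.columns) != required:
        raise FormatError(f"{path}: expected columns {required}, got {list(t.columns)}")
    try:
        pos = pd.to_numeric(t["pos_cM"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric pos_cM") from exc
    table = pd.DataFrame({"marker": t["marker"], "chrom": t["chrom"], "pos_cM": pos})
    if table.isna().any().any():
        raise FormatError(f"{path}: missing values in linkage map")
    return LinkageMap(table)


def write_linkage_map(lmap: LinkageMap, path) -> None:
    lmap.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_genotypes(path, lmap: LinkageMap | None = None) -> GenotypeMatrix:
    """Read a genotype TSV (first column ``line``, one column per marker).

    With a map, marker columns are reordered to map order; markers absent
    from the map raise an error, markers in the map but absent from the file
    are dropped downstream with a warning.
    """
    t = _read_tsv(path)
    if t.columns[0] != "line":
        raise FormatError(f"{path}: first column must be 'line', got {t.columns[0]!r}")
    markers = list(t.columns[1:])
    if len(set(markers)) != len(markers):
        raise FormatError(f"{path}: duplicated marker columns")
    dosage = np.full((len(t), len(markers)), np.nan)
    for j, m in enumerate(markers):
        col = t[m]
        ok = col.isna() | col.isin(["0", "1", "2"])
        if not ok.all():
            bad = col[~ok].iloc[0]
            raise FormatError(f"{path}: marker {m} has dosage {bad!r} outside {{0,1,2,NA}}")
        dosage[:, j] = pd.to_numeric(col).to_numpy()
    geno = GenotypeMatrix(t["line"].tolist(), markers, dosage)
    if lmap is not None:
        unknown = [m for m in markers if m not in set(lmap.markers)]
        if unknown:
            raise FormatError(f"{path}: markers absent from map: {unknown}")
        present = set(markers)
        dropped = [m for m in lmap.markers if m not in present]
        if dropped:
            logger.warning("%s: %d map markers missing from genotype file", path, len(dropped))
        order = [markers.index(m) for m in lmap.markers if m in present]
        geno = geno.subset_markers(order)
    return geno


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.dosage, columns=geno.marker_names)
    # render integral dosages without a decimal point, missing as NA
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.insert(0, "line", geno.line_ids)
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    t = _read_tsv(path)
    if list(t.columns) != ["line", "value"]:
        raise FormatError(f"{path}: expected columns ['line','value'], got {list(t.columns)}")
    try:
        vals = pd.to_numeric(t["value"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric phenotype value") from exc
    return PhenotypeTable(pd.DataFrame({"line": t["line"], "value": vals}))


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_effects(path) -> MarkerEffects:
    """Read an effects TSV; the intercept sits in a reserved ``__intercept__`` row.

    An optional ``__lambda__`` row carries the shrinkage used at estimation.
    """
    t = _read_tsv(path)
    if list(t.columns) != ["marker", "effect"]:
        raise FormatError(f"{path}: expected columns ['marker','effect'], got {list(t.columns)}")
    vals = pd.to_numeric(t["effect"], errors="raise")
    s = pd.Series(vals.to_numpy(), index=t["marker"].tolist())
    if INTERCEPT_ROW not in s.index:
        raise FormatError(f"{path}: missing {INTERCEPT_ROW} row")
    intercept = float(s.pop(INTERCEPT_ROW))
    lam = 1.0
    if "__lambda__" in s.index:
        lam = float(s.pop("__lambda__"))
    return MarkerEffects(intercept=intercept, effects=s, lambda_used=lam)


def write_effects(effects: MarkerEffects, path) -> None:
    rows = [(INTERCEPT_ROW, effects.intercept), ("__lambda__", effects.lambda_used)]
    rows += list(effects.effects.items())
    pd.DataFrame(rows, columns=["marker", "effect"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


_CROSS_COLUMNS = ["parent1", "parent2", "scheme", "t", "mu", "sigma2", "sigma", "s", "U"]


def write_cross_predictions(predictions: list[CrossPrediction], path) -> None:
    """Write one row per cross; floats carry >= 10 significant digits."""
    if not predictions:
        raise ValueError("no cross predictions to write")
    rows = [
        (p.parent1, p.parent2, p.scheme.kind, p.scheme.t, p.mu, p.sigma2, p.sigma, p.s, p.U)
        for p in predictions
    ]
    pd.DataFrame(rows, columns=_CROSS_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_cross_predictions(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False)
    if list(t.columns) != _CROSS_COLUMNS:
        raise FormatError(f"{path}: expected columns {_CROSS_COLUMNS}, got {list(t.columns)}")
    return t


_CONFIG_DEFAULTS = {
    "scheme": "DH",
    "t": 0,
    "p": 0.05,
    "h": 1.0,
    "lambda": "reml",
    "seed": 1,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge YAML run configuration with defaults and CLI overrides."""
    cfg = dict(_CONFIG_DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError(f"{path}: config must be a YAML mapping")
        cfg.update(user)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    cfg["scheme"] = str(cfg["scheme"]).upper()
    MatingScheme(cfg["scheme"], int(cfg["t"]))  # validate early
    return cfg
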