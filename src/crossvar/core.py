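"""Core in-memory containers shared across the package.

Dosage convention: biallelic SNPs coded as counts of an arbitrarily chosen
"alt" allele per line, in {0, 1, 2}; missing values are stored as NaN.
Fully homozygous lines therefore carry only 0 or 2 at non-missing markers,
and the genotypic contribution of a parental homozygote at marker j is
``dosage_j * u_j`` -- twice the additive effect of the allele it carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "LinkageMap",
    "GenotypeMatrix",
    "PhenotypeTable",
    "MarkerEffects",
    "MatingScheme",
    "CrossPrediction",
    "MISSING",
]

#: sentinel used in numeric dosage arrays for missing calls
MISSING = np.nan


class FormatError(ValueError):
    """Raised when an input file or container violates its format contract."""


@dataclass(frozen=True)
class LinkageMap:
    """Ordered marker positions, in centiMorgans, grouped by chromosome.

    ``table`` has columns ``marker``, ``chrom``, ``pos_cM``; rows are sorted
    by position within each chromosome while the first-appearance order of
    chromosomes is preserved.  All pairwise recombination frequencies used in
    the variance formulas derive from these positions.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["marker", "chrom", "pos_cM"]
        if list(t.columns[:3]) != required:
            raise FormatError(f"linkage map needs columns {required}, got {list(t.columns)}")
        if t["marker"].duplicated().any():
            dups = t.loc[t["marker"].duplicated(), "marker"].tolist()
            raise FormatError(f"duplicate marker names in map: {dups}")
        pos = t["pos_cM"].to_numpy(dtype=float)
        if not np.all(np.isfinite(pos)) or np.any(pos < 0):
            raise FormatError("map positions must be finite and >= 0")
        # canonical order: chromosomes in load order, positions nondecreasing within
        chrom_order = {c: i for i, c in enumerate(pd.unique(t["chrom"]))}
        idx = np.lexsort((pos, t["chrom"].map(chrom_order).to_numpy()))
        canon = t.iloc[idx].reset_index(drop=True)
        object.__setattr__(self, "table", canon)

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def chromosomes(self) -> list[str]:
        return pd.unique(self.table["chrom"]).tolist()

    def __len__(self) -> int:
        return len(self.table)

    def chrom_slices(self) -> dict[str, pd.DataFrame]:
        """Per-chromosome sub-tables, in canonical order."""
        return {c: g for c, g in self.table.groupby("chrom", sort=False)}

    def positions(self, markers: list[str]) -> np.ndarray:
        s = self.table.set_index("marker")["pos_cM"]
        return s.loc[markers].to_numpy(dtype=float)

    def restrict(self, markers: list[str]) -> "LinkageMap":
        keep = self.table[self.table["marker"].isin(set(markers))].reset_index(drop=True)
        return LinkageMap(keep)


@dataclass
class GenotypeMatrix:
    """Lines x markers allele-dosage matrix; NaN marks missing calls."""

    line_ids: list[str]
    marker_names: list[str]
    dosage: np.ndarray  # float, shape (n_lines, n_markers)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.line_ids), len(self.marker_names)):
            raise FormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_names)} markers"
            )
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = self.dosage[~valid]
            raise FormatError(f"dosage values outside {{0,1,2,NA}}: {np.unique(bad)}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def row(self, line_id: str) -> np.ndarray:
        return self.dosage[self.line_ids.index(line_id)]

    def subset_lines(self, keep: np.ndarray | list[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            [self.line_ids[i] for i in keep], list(self.marker_names), self.dosage[keep]
        )

    def subset_markers(self, keep: np.ndarray | list[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            list(self.line_ids), [self.marker_names[i] for i in keep], self.dosage[:, keep]
        )

    def is_homozygous(self, line_id: str) -> bool:
        row = self.row(line_id)
        row = row[~np.isnan(row)]
        return bool(np.isin(row, (0.0, 2.0)).all())


@dataclass
class PhenotypeTable:
    """One trait value (BLUP or raw mean) per line."""

    table: pd.DataFrame  # columns: line, value

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns[:2]) != ["line", "value"]:
            raise FormatError(f"phenotype table needs columns ['line','value'], got {list(t.columns)}")
        if t["line"].duplicated().any():
            raise FormatError("duplicate line ids in phenotype table")
        vals = t["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise FormatError("phenotype values must be finite")

    @property
    def line_ids(self) -> list[str]:
        return self.table["line"].tolist()

    @property
    def values(self) -> np.ndarray:
        return self.table["value"].to_numpy(dtype=float)

    def value_for(self, lines: list[str]) -> np.ndarray:
        s = self.table.set_index("line")["value"]
        missing = [l for l in lines if l not in s.index]
        if missing:
            raise FormatError(f"lines without phenotype: {missing}")
        return s.loc[lines].to_numpy(dtype=float)


@dataclass
class MarkerEffects:
    """Intercept and per-marker additive effects from ridge-regression BLUP.

    ``effects[j]`` is the effect per allele dose (dosage coding {0,1,2}), so a
    homozygote contributes ``2 * effects[j]`` at marker j.
    """

    intercept: float
    effects: pd.Series  # index: marker names, values: effect per dose
    lambda_used: float = 1.0

    def __post_init__(self) -> None:
        if not self.lambda_used > 0:
            raise ValueError("lambda_used must be > 0")
        self.effects = self.effects.astype(float)

    @property
    def marker_names(self) -> list[str]:
        return self.effects.index.tolist()

    def predict(self, geno: GenotypeMatrix) -> np.ndarray:
        """Predicted genotypic values beta0 + dosage @ u for complete lines."""
        u = self.effects.reindex(geno.marker_names)
        if u.isna().any():
            missing = u.index[u.isna()].tolist()
            raise ValueError(f"markers without effects: {missing}")
        return self.intercept + geno.dosage @ u.to_numpy()


@dataclass(frozen=True)
class MatingScheme:
    """Line-derivation system: DH or SSD after t generations of intermating.

    ``kind="DH"`` doubles a single gamete of an (F1)^t plant; ``kind="SSD"``
    selfs (F2)^t individuals by single-seed descent to full homozygosity.
    ``t`` counts random-intermating generations applied to the F1 before
    line derivation starts (t=0 is the plain F1-DH / F2-SSD case).
    """

    kind: Literal["DH", "SSD"]
    t: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("DH", "SSD"):
            raise ValueError(f"scheme kind must be 'DH' or 'SSD', got {self.kind!r}")
        if not (isinstance(self.t, (int, np.integer)) and self.t >= 0):
            raise ValueError(f"t must be an integer >= 0, got {self.t!r}")


@dataclass
class CrossPrediction:
    """Predicted distribution summary for the lines derived from one cross."""

    parent1: str
    parent2: str
    scheme: MatingScheme
    mu: float
    sigma2: float
    sigma: float = field(init=False)
    s: float = field(init=False)
    U: float = field(init=False)
    i_used: float = 0.0
    h_used: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2 < -1e-9:
            raise ValueError(f"negative cross variance {self.sigma2}: bug upstream")
        self.sigma2 = max(self.sigma2, 0.0)
        self.sigma = float(np.sqrt(self.sigma2))
        self.s = self.mu + self.i_used * self.sigma
        self.U = self.mu + self.i_used * self.sigma * self.h_used
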