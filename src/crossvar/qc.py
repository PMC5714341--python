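"""Marker and line quality control for the training panel.

Lines are filtered first (kept when at most 10% of their marker calls are
missing), then markers (kept when polymorphic, strictly less than 10%
missing, and gene diversity at least 0.1, computed from non-missing calls
with allele frequency p = mean dosage / 2).  A marker failing several
filters is counted once, under the first failed filter in the order
polymorphism, missingness, diversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GenotypeMatrix

__all__ = ["QCReport", "gene_diversity", "filter_markers", "filter_lines"]


class QCError(ValueError):
    """Raised when filtering removes everything."""

    def __init__(self, message: str, report: "QCReport"):
        super().__init__(message)
        self.report = report


@dataclass
class QCReport:
    n_markers_in: int = 0
    n_markers_out: int = 0
    n_lines_in: int = 0
    n_lines_out: int = 0
    removed_by_filter: dict[str, int] = field(default_factory=dict)
    gene_diversity: dict[str, float] = field(default_factory=dict)

    def check_consistent(self) -> None:
        removed = sum(self.removed_by_filter.values())
        assert self.n_markers_in - self.n_markers_out + self.n_lines_in - self.n_lines_out == removed

    def to_text(self) -> str:
        lines = [
            f"lines: {self.n_lines_in} in, {self.n_lines_out} kept",
            f"markers: {self.n_markers_in} in, {self.n_markers_out} kept",
        ]
        for name, count in self.removed_by_filter.items():
            lines.append(f"  removed ({name}): {count}")
        return "\n".join(lines)

    def to_tsv(self) -> str:
        rows = [
            ("n_lines_in", self.n_lines_in),
            ("n_lines_out", self.n_lines_out),
            ("n_markers_in", self.n_markers_in),
            ("n_markers_out", self.n_markers_out),
        ]
        rows += [(f"removed_{k}", v) for k, v in self.removed_by_filter.items()]
        return "\n".join(f"{k}\t{v}" for k, v in rows)


def gene_diversity(allele_freqs) -> float:
    """Expected heterozygosity 1 - sum(p_i^2) of a locus.

    Accepts the full frequency vector (must sum to 1); for a biallelic
    marker this is 2p(1-p), maximal at 0.5.
    """
    p = np.asarray(allele_freqs, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies sum to {p.sum()}, not 1")
    return float(1.0 - np.sum(p**2))


def _marker_diversity(col: np.ndarray) -> float:
    """Gene diversity of one dosage column, ignoring missing calls."""
    obs = col[~np.isnan(col)]
    p = obs.mean() / 2.0
    return gene_diversity([p, 1.0 - p])


def filter_markers(
    geno: GenotypeMatrix,
    max_missing: float = 0.10,
    min_gene_diversity: float = 0.1,
) -> tuple[GenotypeMatrix, QCReport]:
    """Keep polymorphic markers with missing fraction < max_missing (strict)
    and gene diversity >= min_gene_diversity."""
    if geno.n_markers == 0 or geno.n_lines == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(n_markers_in=geno.n_markers, n_markers_out=0,
                      removed_by_filter={"monomorphic": 0, "missingness": 0, "diversity": 0})
    keep = []
    for j, name in enumerate(geno.marker_names):
        col = geno.dosage[:, j]
        miss = np.isnan(col)
        obs = col[~miss]
        if obs.size == 0 or np.all(obs == obs[0]):
            report.removed_by_filter["monomorphic"] += 1
            continue
        if miss.mean() >= max_missing:
            report.removed_by_filter["missingness"] += 1
            continue
        gd = _marker_diversity(col)
        report.gene_diversity[name] = gd
        if gd < min_gene_diversity:
            report.removed_by_filter["diversity"] += 1
            continue
        keep.append(j)
    report.n_markers_out = len(keep)
    if not keep:
        raise QCError("all markers removed by QC", report)
    return geno.subset_markers(keep), report


def filter_lines(geno: GenotypeMatrix, max_missing: float = 0.10) -> tuple[GenotypeMatrix, QCReport]:
    """Keep lines whose missing fraction is at most max_missing (a line at
    exactly the threshold is kept; removal requires strictly more)."""
    if geno.n_markers == 0 or geno.n_lines == 0:
        raise ValueError("empty genotype matrix")
    miss_frac = geno.missing_mask().mean(axis=1)
    keep = np.flatnonzero(miss_frac <= max_missing)
    report = QCReport(
        n_lines_in=geno.n_lines,
        n_lines_out=len(keep),
        removed_by_filter={"line_missingness": geno.n_lines - len(keep)},
    )
    if keep.size == 0:
        raise QCError("all lines removed by QC", report)
    return geno.subset_lines(keep), report
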