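"""Mean, segregation variance, superior progeny value and usefulness per cross.

For a cross of two homozygous parents, write g_j (h_j) for twice the
additive effect of the maternal (paternal) allele at locus j.  A derived
inbred line carries either g_j or h_j with probability 1/2, so

    mu      = b0 + sum_j (g_j + h_j) / 2
    sigma_g^2 = sum_chrom sum_{j,k} cov(Z_j, Z_k),
    cov(Z_j, Z_k) = (q_jk/2 - 1/4) (g_j - h_j)(g_k - h_k)

with q_jk the parental-origin probability from the mating scheme; the
double sum runs over all ordered locus pairs on a chromosome including
j = k (pairs across chromosomes assort independently and contribute 0).
Crosses are ranked by the superior progeny value s = mu + i sigma_g, or by
the usefulness U = mu + i sigma_g h when the heritability is below one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .core import CrossPrediction, GenotypeMatrix, LinkageMap, MarkerEffects, MatingScheme
from .mating_ld import MapFunction, haldane_r, q_matrix

__all__ = [
    "CrossParentEffects",
    "cross_parent_effects",
    "cross_mean",
    "pair_covariance",
    "cross_variance",
    "selection_intensity",
    "superior_progeny_value",
    "usefulness",
    "predict_cross",
    "predict_all_crosses",
]

logger = logging.getLogger(__name__)


@dataclass
class CrossParentEffects:
    """Per-marker genotypic contributions g_j, h_j of the two parents."""

    beta0: float
    markers: list[str]
    g: np.ndarray  # maternal dosage * effect per dose
    h: np.ndarray  # paternal dosage * effect per dose


def cross_parent_effects(
    maternal: np.ndarray,
    paternal: np.ndarray,
    effects: MarkerEffects,
    marker_names: list[str],
    parent_ids: tuple[str, str] = ("maternal", "paternal"),
) -> CrossParentEffects:
    """Build g_j, h_j from two homozygous dosage vectors.

    Markers with a missing dosage in either parent are excluded from both
    sums with a warning; heterozygous calls are an error.
    """
    maternal = np.asarray(maternal, dtype=float)
    paternal = np.asarray(paternal, dtype=float)
    for dose, pid in ((maternal, parent_ids[0]), (paternal, parent_ids[1])):
        het = np.flatnonzero(dose == 1.0)
        if het.size:
            raise ValueError(
                f"parent {pid} is heterozygous at marker {marker_names[het[0]]}"
            )
    u = effects.effects.reindex(marker_names)
    if u.isna().any():
        raise ValueError(f"markers without effects: {u.index[u.isna()].tolist()}")
    keep = ~(np.isnan(maternal) | np.isnan(paternal))
    if not keep.all():
        dropped = [m for m, k in zip(marker_names, keep) if not k]
        logger.warning(
            "cross %s x %s: dropping %d markers with missing parental dosage",
            parent_ids[0], parent_ids[1], len(dropped),
        )
    uv = u.to_numpy()[keep]
    return CrossParentEffects(
        beta0=effects.intercept,
        markers=[m for m, k in zip(marker_names, keep) if k],
        g=maternal[keep] * uv,
        h=paternal[keep] * uv,
    )


def cross_mean(effects: CrossParentEffects) -> float:
    """mu = b0 + sum_j (g_j + h_j)/2: the midpoint of the parental values."""
    return float(effects.beta0 + 0.5 * np.sum(effects.g + effects.h))


def pair_covariance(g_j: float, h_j: float, g_k: float, h_k: float, q_jk: float) -> float:
    """cov(Z_j, Z_k) = (q/2 - 1/4)(g_j - h_j)(g_k - h_k)."""
    if not 0.0 <= q_jk <= 1.0:
        raise ValueError("q_jk must lie in [0, 1]")
    return (0.5 * q_jk - 0.25) * (g_j - h_j) * (g_k - h_k)


def cross_variance(
    effects: CrossParentEffects,
    lmap: LinkageMap,
    scheme: MatingScheme,
    map_function: MapFunction = haldane_r,
) -> float:
    """Segregation variance: double sum of pair covariances per chromosome.

    O(L^2) per chromosome, exact, no distance cutoff.  The diagonal term is
    the single-locus variance (g-h)^2/4; markers monomorphic in the cross
    (g = h) contribute nothing.
    """
    known = set(lmap.markers)
    missing = [m for m in effects.markers if m not in known]
    if missing:
        raise ValueError(f"markers absent from linkage map: {missing}")
    sub = lmap.restrict(effects.markers)
    delta = dict(zip(effects.markers, effects.g - effects.h))
    total = 0.0
    for _, chrom_table in sub.chrom_slices().items():
        names = chrom_table["marker"].tolist()
        d = np.array([delta[m] for m in names])
        if not np.any(d):
            continue
        q = q_matrix(scheme, chrom_table["pos_cM"].to_numpy(), map_function)
        total += float(d @ (0.5 * q - 0.25) @ d)
    if total < -1e-9:
        raise ValueError(f"cross variance {total} is materially negative: bug upstream")
    if total < 0:
        logger.warning("clamping tiny negative cross variance %.3g to 0", total)
        total = 0.0
    return total


def selection_intensity(p: float) -> float:
    """Mean of the upper fraction p of a standard normal: i = phi(z_p)/p."""
    if not 0.0 < p <= 1.0:
        raise ValueError("selected fraction p must lie in (0, 1]")
    if p == 1.0:
        return 0.0
    z = stats.norm.isf(p)
    return float(stats.norm.pdf(z) / p)


def superior_progeny_value(mu: float, sigma: float, i: float) -> float:
    """s = mu + i sigma_g: expected value of the selected fraction."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return mu + i * sigma


def usefulness(mu: float, sigma: float, i: float, h: float) -> float:
    """U = mu + i sigma_g h, with h the square root of the heritability."""
    if not 0.0 <= h <= 1.0:
        raise ValueError("h must lie in [0, 1]")
    return mu + i * sigma * h


def predict_cross(
    parents: GenotypeMatrix,
    parent1: str,
    parent2: str,
    effects: MarkerEffects,
    lmap: LinkageMap,
    scheme: MatingScheme,
    p: float = 0.05,
    h: float = 1.0,
    map_function: MapFunction = haldane_r,
) -> CrossPrediction:
    cpe = cross_parent_effects(
        parents.row(parent1), parents.row(parent2), effects, parents.marker_names,
        parent_ids=(parent1, parent2),
    )
    mu = cross_mean(cpe)
    sigma2 = cross_variance(cpe, lmap, scheme, map_function)
    i = selection_intensity(p)
    return CrossPrediction(
        parent1=parent1, parent2=parent2, scheme=scheme,
        mu=mu, sigma2=sigma2, i_used=i, h_used=h,
    )


def predict_all_crosses(
    parents: GenotypeMatrix,
    effects: MarkerEffects,
    lmap: LinkageMap,
    scheme: MatingScheme,
    p: float = 0.05,
    h: float = 1.0,
    map_function: MapFunction = haldane_r,
) -> list[CrossPrediction]:
    """One prediction per unordered parent pair, sorted by s descending
    (ties broken lexicographically by parent ids)."""
    if parents.n_lines < 2:
        raise ValueError("need at least 2 parents")
    preds = [
        predict_cross(parents, p1, p2, effects, lmap, scheme, p, h, map_function)
        for p1, p2 in combinations(parents.line_ids, 2)
    ]
    preds.sort(key=lambda c: (-c.s, c.parent1, c.parent2))
    return preds
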