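"""Recombination frequencies, expected LD, and parental-origin probabilities.

For two loci j, k in a population of inbred lines derived from a biparental
cross, everything needed by the variance formula reduces to

    q_jk = P(locus k carries the maternal allele | locus j does) = 1/2 + 2 D_jk,

where D_jk is the expected LD coefficient between the parental-origin
indicators (allele frequencies 1/2).  D_jk depends only on the recombination
frequency r_jk and the mating scheme:

    (F1)^t-DH :  D = (1-2r)/4 * (1-r)^t
    (F2)^t-SSD:  D = (1-2r)/(4(1+2r)) * (1-r)^t

The SSD factor 1/(1+2r) is the Haldane-Waddington fixpoint of repeated
selfing; the (1-r)^t factor is the per-generation LD decay during random
intermating.  Distances map to r through a pluggable mapping function
(Haldane by default, assuming no crossover interference).

All functions are numpy ufunc-style: scalars in, scalar out; arrays in,
elementwise arrays out.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .core import MatingScheme

__all__ = [
    "haldane_r",
    "ld_dh",
    "ld_ssd",
    "q_from_ld",
    "q_jk",
    "q_matrix",
]

#: signature of a genetic-map function: distance in cM -> recombination frequency
MapFunction = Callable[[np.ndarray], np.ndarray]


def haldane_r(distance_cM):
    """Haldane mapping function r = (1 - exp(-2 d)) / 2, d in Morgans.

    Input distances are in centiMorgans; the cM -> Morgan conversion (/100)
    happens here and nowhere else.
    """
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0 cM")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r if r.ndim else float(r)


def _check_r(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination frequency must lie in [0, 0.5]")
    return r


def ld_dh(r, t: int):
    """Expected LD among (F1)^t-DH lines: D = (1-2r)/4 * (1-r)^t."""
    r = _check_r(r)
    if t < 0:
        raise ValueError("t must be >= 0")
    D = (1.0 - 2.0 * r) / 4.0 * (1.0 - r) ** t
    return D if D.ndim else float(D)


def ld_ssd(r, t: int):
    """Expected LD among (F2)^t-SSD lines: D = (1-2r)/(4(1+2r)) * (1-r)^t."""
    r = _check_r(r)
    if t < 0:
        raise ValueError("t must be >= 0")
    D = (1.0 - 2.0 * r) / (4.0 * (1.0 + 2.0 * r)) * (1.0 - r) ** t
    return D if D.ndim else float(D)


def q_from_ld(D):
    """q = 1/2 + 2 D, valid for parental-origin indicators with freq 1/2."""
    D = np.asarray(D, dtype=float)
    if np.any((D < -0.25 - 1e-12) | (D > 0.25 + 1e-12)):
        raise ValueError("LD coefficient must lie in [-0.25, 0.25]")
    q = 0.5 + 2.0 * D
    return q if q.ndim else float(q)


def q_jk(scheme: MatingScheme, distance_cM, map_function: MapFunction = haldane_r):
    """Conditional parental-origin probability for two loci at a map distance.

    Evaluates the closed forms directly:
    DH:  q = 1/2 + (1-2r)/2 * (1-r)^t
    SSD: q = 1/2 + (1-2r)/(2+4r) * (1-r)^t
    which equal q_from_ld applied to ld_dh / ld_ssd.
    """
    r = np.asarray(map_function(distance_cM), dtype=float)
    decay = (1.0 - r) ** scheme.t
    if scheme.kind == "DH":
        q = 0.5 + (1.0 - 2.0 * r) / 2.0 * decay
    else:
        q = 0.5 + (1.0 - 2.0 * r) / (2.0 + 4.0 * r) * decay
    return q if q.ndim else float(q)


def q_matrix(
    scheme: MatingScheme,
    positions_cM: np.ndarray,
    map_function: MapFunction = haldane_r,
) -> np.ndarray:
    """Pairwise q_jk for markers on one chromosome; diagonal q_jj = 1.

    A locus trivially shares parental origin with itself, so the diagonal is
    1 regardless of scheme, which makes the diagonal covariance terms the
    single-locus variances (g-h)^2/4.
    """
    pos = np.asarray(positions_cM, dtype=float)
    dist = np.abs(pos[:, None] - pos[None, :])
    q = np.asarray(q_jk(scheme, dist, map_function))
    np.fill_diagonal(q, 1.0)
    return q
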