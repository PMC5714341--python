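"""Simulation and enumeration oracles for the closed-form cross moments.

Three independent routes verify the analytical mean and variance:

* exact enumeration of all 2^L gametes for small F1-DH cases;
* an exact two-locus diplotype recursion under selfing, whose fixpoint is
  the Haldane-Waddington LD D/(1+2r);
* Monte-Carlo meiosis for DH and SSD with optional intermating generations.

Meiosis follows a count-location process without crossover interference:
the number of crossovers on a chromosome is Poisson with mean equal to the
map length in Morgans, and crossover locations are i.i.d. uniform along the
chromosome.  This is the stochastic model whose two-locus statistics match
the Haldane mapping function exactly.

Parents are homozygous, so progeny genomes are tracked as binary
parental-origin vectors (0 = allele from parent 1, 1 = from parent 2).
The intermating generations run in a finite population (default 200
individuals; use a larger size when validating the infinite-population
formulas, which ignore drift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix, LinkageMap, MarkerEffects, MatingScheme
from .cross_metrics import CrossParentEffects

__all__ = [
    "SimulatedPopulation",
    "simulate_gamete",
    "simulate_population",
    "exhaustive_dh_variance",
    "two_locus_selfing_fixpoint",
    "mc_variance_estimate",
    "simulate_cross_summary",
]


@dataclass
class SimulatedPopulation:
    """Homozygous progeny dosages for one cross, possibly replicated.

    ``dosage`` has shape (n_replicates, n_progeny, n_markers) with values in
    {0, 2}; genotypic values are recomputable as b0 + dosage @ u.
    """

    dosage: np.ndarray
    marker_names: list[str]
    scheme: MatingScheme
    n_progeny: int
    n_replicates: int
    seed: int

    def genotypic_values(self, effects: MarkerEffects) -> np.ndarray:
        u = effects.effects.reindex(self.marker_names)
        if u.isna().any():
            raise ValueError("effects missing for simulated markers")
        return effects.intercept + self.dosage @ u.to_numpy()


# ---------------------------------------------------------------------------
# meiosis


def _chrom_blocks(lmap: LinkageMap) -> list[tuple[slice, np.ndarray]]:
    """(marker slice, positions in Morgans) per chromosome, in map order."""
    blocks = []
    start = 0
    for _, tab in lmap.chrom_slices().items():
        L = len(tab)
        blocks.append((slice(start, start + L), tab["pos_cM"].to_numpy() / 100.0))
        start += L
    return blocks


def _meiosis_patterns(pos_M: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n parental-origin patterns for one chromosome's markers, shape (n, L).

    Count-location crossover process: Poisson(count) with mean = marker span
    in Morgans, uniform locations; the pattern flips at each crossover and
    starts from a fair coin.  Crossovers outside the marker span cannot be
    observed and are not generated.
    """
    L = len(pos_M)
    span = float(pos_M[-1] - pos_M[0]) if L > 1 else 0.0
    start = rng.integers(0, 2, size=n, dtype=np.int8)
    if span <= 0.0:
        return np.repeat(start[:, None], L, axis=1)
    counts = rng.poisson(span, size=n)
    total = int(counts.sum())
    flips = np.zeros((n, L), dtype=np.int64)
    if total:
        locs = rng.uniform(pos_M[0], pos_M[-1], size=total)
        owner = np.repeat(np.arange(n), counts)
        # a crossover strictly before marker m flips markers m..L-1
        interval = np.searchsorted(pos_M, locs, side="left")
        inside = interval < L
        np.add.at(flips, (owner[inside], interval[inside]), 1)
    pattern = (start[:, None] + np.cumsum(flips, axis=1)) % 2
    return pattern.astype(np.int8)


def simulate_gamete(
    parent_haplotypes: tuple[np.ndarray, np.ndarray],
    lmap: LinkageMap,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from one meiosis, markers in map order."""
    h1 = np.asarray(parent_haplotypes[0])
    h2 = np.asarray(parent_haplotypes[1])
    if h1.shape != h2.shape or len(h1) != len(lmap):
        raise ValueError("haplotype length must equal the map's marker count")
    gamete = np.empty_like(h1)
    for sl, pos in _chrom_blocks(lmap):
        pat = _meiosis_patterns(pos, 1, rng)[0]
        gamete[sl] = np.where(pat == 0, h1[sl], h2[sl])
    return gamete


def _meiosis_batch(
    hap1: np.ndarray, hap2: np.ndarray, blocks, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from each of n individuals; haplotype inputs shape (n, L)."""
    n, L = hap1.shape
    out = np.empty((n, L), dtype=hap1.dtype)
    for sl, pos in blocks:
        pat = _meiosis_patterns(pos, n, rng)
        out[:, sl] = np.where(pat == 0, hap1[:, sl], hap2[:, sl])
    return out


# ---------------------------------------------------------------------------
# population simulation


def _intermate(pop: np.ndarray, t: int, n_im: int, blocks, rng) -> np.ndarray:
    """t rounds of random mating; pop shape (N, 2, L) of origin haplotypes."""
    for _ in range(t):
        i1 = rng.integers(0, len(pop), size=n_im)
        i2 = rng.integers(0, len(pop), size=n_im)
        g1 = _meiosis_batch(pop[i1, 0], pop[i1, 1], blocks, rng)
        g2 = _meiosis_batch(pop[i2, 0], pop[i2, 1], blocks, rng)
        pop = np.stack([g1, g2], axis=1)
    return pop


def _one_replicate(
    blocks,
    L: int,
    scheme: MatingScheme,
    n_progeny: int,
    rng: np.random.Generator,
    n_im: int,
    n_self: int,
) -> np.ndarray:
    """Origin vectors (n_progeny, L) of fully homozygous derived lines."""
    f1 = np.stack(
        [np.zeros((1, L), dtype=np.int8), np.ones((1, L), dtype=np.int8)], axis=1
    )
    pop = _intermate(f1, scheme.t, n_im, blocks, rng) if scheme.t else f1
    if scheme.kind == "DH":
        idx = rng.integers(0, len(pop), size=n_progeny)
        return _meiosis_batch(pop[idx, 0], pop[idx, 1], blocks, rng)
    # SSD: form the F2-stage individuals, then self by single-seed descent
    i1 = rng.integers(0, len(pop), size=n_progeny)
    i2 = rng.integers(0, len(pop), size=n_progeny)
    hap1 = _meiosis_batch(pop[i1, 0], pop[i1, 1], blocks, rng)
    hap2 = _meiosis_batch(pop[i2, 0], pop[i2, 1], blocks, rng)
    for _ in range(n_self):
        new1 = _meiosis_batch(hap1, hap2, blocks, rng)
        new2 = _meiosis_batch(hap1, hap2, blocks, rng)
        hap1, hap2 = new1, new2
    # close residual heterozygosity with a fair coin per locus (F-infinity limit)
    coin = rng.integers(0, 2, size=hap1.shape, dtype=np.int8)
    return np.where(coin == 0, hap1, hap2)


def simulate_population(
    parents: tuple[np.ndarray, np.ndarray],
    lmap: LinkageMap,
    scheme: MatingScheme,
    n_progeny: int,
    seed: int,
    n_replicates: int = 1,
    n_im: int = 200,
    n_self: int = 10,
    marker_names: list[str] | None = None,
) -> SimulatedPopulation:
    """Simulate homozygous lines derived from a cross of two homozygous parents.

    ``parents`` are the two dosage vectors ({0, 2} at non-missing markers) in
    map order.  Replicate r uses its own generator seeded ``seed + r`` so
    replicates are independent and individually reproducible.
    """
    dos1 = np.asarray(parents[0], dtype=float)
    dos2 = np.asarray(parents[1], dtype=float)
    if dos1.shape != dos2.shape or len(dos1) != len(lmap):
        raise ValueError("parent dosage vectors must match the map's marker count")
    for d in (dos1, dos2):
        if not np.isin(d, (0.0, 2.0)).all():
            raise ValueError("parents must be fully homozygous with no missing calls")
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    blocks = _chrom_blocks(lmap)
    L = len(lmap)
    dosage = np.empty((n_replicates, n_progeny, L))
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed + rep)
        origin = _one_replicate(blocks, L, scheme, n_progeny, rng, n_im, n_self)
        dosage[rep] = np.where(origin == 0, dos1, dos2)
    return SimulatedPopulation(
        dosage=dosage,
        marker_names=marker_names or lmap.markers,
        scheme=scheme,
        n_progeny=n_progeny,
        n_replicates=n_replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# exact oracles


def _haldane_interval_r(pos_M: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * np.diff(pos_M)))


def exhaustive_dh_variance(
    effects: CrossParentEffects, lmap: LinkageMap, max_loci: int = 20
) -> tuple[float, float]:
    """Exact mean and variance of F1-DH genotypic values by 2^L enumeration.

    Uses the Markov property of the crossover pattern along a chromosome
    (implied by the count-location process): a gamete pattern's probability
    is 1/2 times the product over adjacent intervals of r_i (switch) or
    1 - r_i (no switch).  Chromosomes combine by independence.
    """
    sub = lmap.restrict(effects.markers)
    g = dict(zip(effects.markers, effects.g))
    h = dict(zip(effects.markers, effects.h))
    mean_total = effects.beta0
    var_total = 0.0
    for _, tab in sub.chrom_slices().items():
        names = tab["marker"].tolist()
        L = len(names)
        if L > max_loci:
            raise ValueError(
                f"{L} loci on one chromosome exceeds the 2^{max_loci} enumeration "
                "limit; use the Monte-Carlo path"
            )
        gv = np.array([g[m] for m in names])
        hv = np.array([h[m] for m in names])
        r = _haldane_interval_r(tab["pos_cM"].to_numpy() / 100.0)
        codes = np.arange(2**L, dtype=np.uint32)
        pattern = (codes[:, None] >> np.arange(L)) & 1  # (2^L, L) in {0,1}
        switches = pattern[:, 1:] != pattern[:, :-1]
        prob = 0.5 * np.prod(np.where(switches, r, 1.0 - r), axis=1)
        values = pattern @ hv + (1 - pattern) @ gv
        m1 = float(prob @ values)
        mean_total += m1
        var_total += float(prob @ values**2) - m1**2
    return mean_total, var_total


def two_locus_selfing_fixpoint(
    r: float, D_init: float, tol: float = 1e-12, max_iter: int = 10_000
) -> float:
    """LD among inbred lines from selfing a random-mating population to fixation.

    Iterates the exact two-locus diplotype-frequency recursion under selfing
    (ordered gamete pairs; meiosis with recombination r) from a population
    with gamete-level LD ``D_init`` and allele frequencies 1/2, until total
    heterozygosity falls below ``tol``; returns the LD among the fixed lines.
    The analytical fixpoint is D_init / (1 + 2 r).
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError("r must lie in [0, 0.5]")
    if not -0.25 <= D_init <= 0.25:
        raise ValueError("D_init must lie in [-0.25, 0.25]")
    # gametes 0..3 as bit pairs (locus j, locus k); 0=both maternal, 3=both paternal
    c = np.array([0.25 + D_init, 0.25 - D_init, 0.25 - D_init, 0.25 + D_init])
    # meiosis gamete distribution per ordered diplotype (a, b)
    meiosis = np.zeros((4, 4, 4))
    for a in range(4):
        for b in range(4):
            xa, ya = a >> 1, a & 1
            xb, yb = b >> 1, b & 1
            meiosis[a, b, (xa << 1) | ya] += (1.0 - r) / 2.0
            meiosis[a, b, (xb << 1) | yb] += (1.0 - r) / 2.0
            meiosis[a, b, (xa << 1) | yb] += r / 2.0
            meiosis[a, b, (xb << 1) | ya] += r / 2.0
    f = np.outer(c, c)  # F2-stage ordered diplotype frequencies
    fixed_states = np.eye(4, dtype=bool)
    for _ in range(max_iter):
        het = float(f[~fixed_states].sum())
        if het < tol:
            break
        new = np.zeros_like(f)
        for a in range(4):
            for b in range(4):
                if f[a, b] == 0.0:
                    continue
                m = meiosis[a, b]
                new += f[a, b] * np.outer(m, m)
        f = new
    else:
        raise RuntimeError(f"selfing recursion did not fix in {max_iter} iterations")
    cfix = np.diag(f) / np.diag(f).sum()
    return float(cfix[0] - (cfix[0] + cfix[1]) * (cfix[0] + cfix[2]))


# ---------------------------------------------------------------------------
# Monte-Carlo summaries


def mc_variance_estimate(
    pop: SimulatedPopulation, effects: MarkerEffects
) -> tuple[float, float, float]:
    """Replicate-averaged mean and variance of the genotypic values.

    Each replicate contributes its sample mean and (n-1)-denominator
    variance; returns (mean, variance, SE of the variance estimate).  With a
    single replicate the SE falls back to the normal-theory approximation
    s^2 sqrt(2/(n-1)).
    """
    if pop.n_progeny < 2:
        raise ValueError("need at least 2 progeny per replicate")
    values = pop.genotypic_values(effects)  # (reps, n)
    rep_means = values.mean(axis=1)
    rep_vars = values.var(axis=1, ddof=1)
    mean = float(rep_means.mean())
    var = float(rep_vars.mean())
    if pop.n_replicates >= 2:
        se = float(rep_vars.std(ddof=1) / np.sqrt(pop.n_replicates))
    else:
        se = float(var * np.sqrt(2.0 / (pop.n_progeny - 1)))
    return mean, var, se


def simulate_cross_summary(
    parents: GenotypeMatrix,
    parent1: str,
    parent2: str,
    effects: MarkerEffects,
    lmap: LinkageMap,
    scheme: MatingScheme,
    n_progeny: int,
    n_replicates: int,
    seed: int,
    n_im: int = 200,
    n_self: int = 10,
) -> tuple[float, float, float]:
    """Simulated (mean, variance, SE of variance) for one named cross."""
    pop = simulate_population(
        (parents.row(parent1), parents.row(parent2)),
        lmap.restrict(parents.marker_names),
        scheme,
        n_progeny=n_progeny,
        seed=seed,
        n_replicates=n_replicates,
        n_im=n_im,
        n_self=n_self,
        marker_names=parents.marker_names,
    )
    return mc_variance_estimate(pop, effects)
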