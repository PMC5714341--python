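"""Synthetic linkage maps, training panels, phenotypes, and parent lines.

The generator emulates the statistical structure a cross-prediction study
needs: a diverse training panel with marker-marker LD, an additive genetic
architecture with a controllable number of QTL among the markers, trait
values on a flowering-time-like scale, and a set of fully homozygous
candidate parents drawn from the same population.

LD in the panel is induced mechanistically: founder haplotypes are drawn
with per-marker allele frequencies uniform on (0.1, 0.9), then the panel is
bred through a few generations of random mating with recombination along
the same linkage map used downstream.  Independent-marker draws would make
effect estimation unrealistically easy and leave the pairwise variance
terms untested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, LinkageMap, MarkerEffects, PhenotypeTable
from .sim_oracle import _chrom_blocks, _meiosis_batch

__all__ = ["SynthConfig", "SynthDataset", "generate_dataset", "nam_like_preset"]


@dataclass(frozen=True)
class SynthConfig:
    n_chromosomes: int = 10
    chromosome_length_cM: float = 140.0
    #: markers per chromosome; an int, or one count per chromosome
    n_markers_per_chromosome: int | Sequence[int] = 33
    n_training_lines: int = 258
    n_parents: int = 26
    n_qtl: int = 40
    #: standard deviation of the nonzero per-dose QTL effects
    effect_sd: float = 0.3
    heritability: float = 0.8
    missing_rate: float = 0.0
    seed: int = 0
    #: founder haplotypes and random-mating generations shaping panel LD
    n_founders: int = 16
    n_mating_generations: int = 5
    #: trait intercept (days-to-flowering-like scale)
    intercept: float = 70.0

    def __post_init__(self) -> None:
        counts = self.marker_counts()
        if self.n_chromosomes < 1 or any(c < 1 for c in counts):
            raise ValueError("chromosome and marker counts must be >= 1")
        if len(counts) != self.n_chromosomes:
            raise ValueError("one marker count per chromosome required")
        if self.n_training_lines < 1 or self.n_parents < 1 or self.n_founders < 2:
            raise ValueError("line counts must be >= 1 (founders >= 2)")
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must lie in (0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.n_qtl <= sum(counts):
            raise ValueError("n_qtl must not exceed the marker count")

    def marker_counts(self) -> list[int]:
        if isinstance(self.n_markers_per_chromosome, (int, np.integer)):
            return [int(self.n_markers_per_chromosome)] * self.n_chromosomes
        return [int(c) for c in self.n_markers_per_chromosome]

    @property
    def n_markers(self) -> int:
        return sum(self.marker_counts())


class SynthDataset(NamedTuple):
    linkage_map: LinkageMap
    training: GenotypeMatrix
    phenotypes: PhenotypeTable
    parents: GenotypeMatrix
    true_effects: MarkerEffects


def nam_like_preset(seed: int = 0) -> SynthConfig:
    """A desk-scale mimic of a maize NAM-style design.

    10 chromosomes of 140 cM (1400 cM genome), 325 markers (about one every
    4.3 cM), 258 training lines, 26 homozygous parents.
    """
    return SynthConfig(
        n_chromosomes=10,
        chromosome_length_cM=140.0,
        n_markers_per_chromosome=(33, 33, 33, 33, 33, 32, 32, 32, 32, 32),
        n_training_lines=258,
        n_parents=26,
        seed=seed,
    )


def _random_map(cfg: SynthConfig, rng: np.random.Generator) -> LinkageMap:
    rows = []
    for ci, count in enumerate(cfg.marker_counts(), start=1):
        pos = np.sort(rng.uniform(0.0, cfg.chromosome_length_cM, size=count))
        for mi, p in enumerate(pos, start=1):
            rows.append((f"m{ci}_{mi}", str(ci), float(p)))
    return LinkageMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM"]))


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Generate one fully reproducible synthetic dataset from a config.

    Phenotypes follow y = b0 + Z u + e with the residual variance scaled so
    that var(Zu) / (var(Zu) + var(e)) equals the configured heritability on
    the realized panel.  Parents are doubled gametes of panel individuals,
    hence fully homozygous.  Missing calls (if any) are placed in the
    training panel only; parents are delivered complete.
    """
    rng = np.random.default_rng(cfg.seed)
    lmap = _random_map(cfg, rng)
    L = len(lmap)
    blocks = _chrom_blocks(lmap)

    # founder haplotypes with intermediate allele frequencies
    freqs = rng.uniform(0.1, 0.9, size=L)
    founders = (rng.random((cfg.n_founders, L)) < freqs).astype(np.int8)

    # breed the panel: random founder pairs, then random mating with recombination
    n_pop = max(cfg.n_training_lines, cfg.n_parents, 2)
    hap1 = founders[rng.integers(0, cfg.n_founders, size=n_pop)]
    hap2 = founders[rng.integers(0, cfg.n_founders, size=n_pop)]
    for _ in range(cfg.n_mating_generations):
        i1 = rng.integers(0, n_pop, size=n_pop)
        i2 = rng.integers(0, n_pop, size=n_pop)
        new1 = _meiosis_batch(hap1[i1], hap2[i1], blocks, rng)
        new2 = _meiosis_batch(hap1[i2], hap2[i2], blocks, rng)
        hap1, hap2 = new1, new2

    train_dosage = (hap1[: cfg.n_training_lines] + hap2[: cfg.n_training_lines]).astype(float)
    train_ids = [f"L{i + 1:03d}" for i in range(cfg.n_training_lines)]

    # parents: double one gamete per randomly chosen panel individual
    idx = rng.integers(0, n_pop, size=cfg.n_parents)
    gametes = _meiosis_batch(hap1[idx], hap2[idx], blocks, rng)
    parent_dosage = 2.0 * gametes
    parent_ids = [f"P{i + 1:02d}" for i in range(cfg.n_parents)]

    # additive architecture on a subset of markers
    u = np.zeros(L)
    qtl = rng.choice(L, size=cfg.n_qtl, replace=False)
    u[qtl] = rng.normal(0.0, cfg.effect_sd, size=cfg.n_qtl)
    true_effects = MarkerEffects(
        intercept=cfg.intercept,
        effects=pd.Series(u, index=lmap.markers),
        lambda_used=1.0,
    )

    genetic = train_dosage @ u
    var_g = float(np.var(genetic))
    if cfg.heritability < 1.0 and var_g > 0.0:
        sd_e = np.sqrt(var_g * (1.0 - cfg.heritability) / cfg.heritability)
    else:
        sd_e = 0.0
    y = cfg.intercept + genetic + rng.normal(0.0, sd_e, size=cfg.n_training_lines)
    pheno = PhenotypeTable(pd.DataFrame({"line": train_ids, "value": y}))

    if cfg.missing_rate > 0.0:
        mask = rng.random(train_dosage.shape) < cfg.missing_rate
        train_dosage[mask] = np.nan

    training = GenotypeMatrix(train_ids, lmap.markers, train_dosage)
    parents = GenotypeMatrix(parent_ids, lmap.markers, parent_dosage)
    return SynthDataset(lmap, training, pheno, parents, true_effects)
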