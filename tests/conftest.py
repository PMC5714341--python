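import numpy as np
import pandas as pd
import pytest

from crossvar.core import GenotypeMatrix, LinkageMap, MarkerEffects
from crossvar.cross_metrics import CrossParentEffects


def make_map(positions_cM, chrom="1", prefix="m"):
    """Single- or multi-chromosome map from position lists."""
    if isinstance(positions_cM, dict):
        rows = [
            (f"{prefix}{c}_{i}", c, p)
            for c, pos in positions_cM.items()
            for i, p in enumerate(pos)
        ]
    else:
        rows = [(f"{prefix}{i}", chrom, p) for i, p in enumerate(positions_cM)]
    return LinkageMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_cM"]))


def random_dh_case(rng, n_loci, span_cM=100.0, beta0=0.0):
    """Random one-chromosome cross: map, effects container, parent dosages."""
    lmap = make_map(np.sort(rng.uniform(0.0, span_cM, size=n_loci)))
    u = rng.normal(0.0, 0.5, size=n_loci)
    d1 = 2.0 * rng.integers(0, 2, size=n_loci)
    d2 = 2.0 * rng.integers(0, 2, size=n_loci)
    cpe = CrossParentEffects(
        beta0=beta0, markers=lmap.markers, g=d1 * u, h=d2 * u
    )
    return lmap, cpe, (d1, d2), u


@pytest.fixture
def tiny_map():
    return make_map([0.0, 4.3, 10.0])


@pytest.fixture
def toy_training():
    """6 lines x 4 markers, no missing, clearly polymorphic."""
    rng = np.random.default_rng(11)
    dosage = rng.integers(0, 3, size=(6, 4)).astype(float)
    dosage[:, 0] = [0, 2, 0, 2, 1, 1]  # guarantee polymorphism on marker 0
    return GenotypeMatrix([f"L{i}" for i in range(6)], [f"m{i}" for i in range(4)], dosage)


def effects_from(u, markers, beta0=0.0, lam=1.0):
    return MarkerEffects(intercept=beta0, effects=pd.Series(u, index=markers), lambda_used=lam)
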