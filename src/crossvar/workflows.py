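"""End-to-end study workflows combining the generator, estimator, predictor
and simulator."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MatingScheme
from .cross_metrics import predict_cross
from .effects import choose_lambda, impute_missing, rrblup_solve
from .sim_oracle import simulate_cross_summary
from .synth_fixtures import generate_dataset, nam_like_preset

__all__ = ["nam_like_variance_comparison"]


def nam_like_variance_comparison(
    seed: int,
    n_progeny: int = 200,
    n_replicates: int = 25,
    scheme: MatingScheme = MatingScheme("DH", 0),
) -> tuple[pd.DataFrame, dict]:
    """Analytical vs simulated cross moments on a NAM-style synthetic design.

    Generates the nam-like dataset, estimates marker effects by RR-BLUP with
    REML shrinkage, then for every cross of the first parent with the
    remaining parents computes the closed-form mean and variance and a
    Monte-Carlo estimate from ``n_progeny`` DH/SSD progeny per replicate,
    averaging ``n_replicates`` replicate variances.  Returns the per-cross
    table and summary statistics (Pearson correlations of means and
    variances, and the replicate-averaged runtime-free moments).
    """
    ds = generate_dataset(nam_like_preset(seed=seed))
    geno = impute_missing(ds.training)
    lam = choose_lambda(geno, ds.phenotypes, "reml")
    eff = rrblup_solve(geno, ds.phenotypes, lam)

    common = ds.parents.line_ids[0]
    rows = []
    for k, other in enumerate(ds.parents.line_ids[1:]):
        pred = predict_cross(ds.parents, common, other, eff, ds.linkage_map, scheme)
        mu_sim, var_sim, se = simulate_cross_summary(
            ds.parents, common, other, eff, ds.linkage_map, scheme,
            n_progeny=n_progeny, n_replicates=n_replicates,
            seed=seed + 1000 * (k + 1),
        )
        rows.append((common, other, pred.mu, pred.sigma2, mu_sim, var_sim, se))
    table = pd.DataFrame(
        rows,
        columns=["parent1", "parent2", "mu", "sigma2", "mu_sim", "sigma2_sim", "se_sigma2"],
    )
    summary = {
        "lambda": lam,
        "n_crosses": len(table),
        "r_mean": float(np.corrcoef(table["mu"], table["mu_sim"])[0, 1]),
        "r_variance": float(np.corrcoef(table["sigma2"], table["sigma2_sim"])[0, 1]),
    }
    return table, summary
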