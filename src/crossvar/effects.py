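"""Ridge-regression BLUP of additive marker effects.

The model is y = 1 b0 + Z u + e with raw {0,1,2} dosages in Z (the explicit
intercept absorbs the column means), u ~ N(0, s_u^2 I), e ~ N(0, s_e^2 I),
and shrinkage lambda = s_e^2 / s_u^2.  Effects solve the mixed-model
equations

    [ 1'1      1'Z       ] [ b0 ]   [ 1'y ]
    [ Z'1   Z'Z + lambda I] [ u  ] = [ Z'y ]

For m <= n the (m+1)-dimensional symmetric system is solved directly; for
m > n an equivalent n-dimensional dual (kernel) solve is used.  Both paths
agree to high precision.

lambda can be fixed by the caller or estimated by restricted maximum
likelihood (REML) on the profile likelihood in log-lambda, using the
eigendecomposition of the intercept-projected ZZ'.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .core import GenotypeMatrix, MarkerEffects, PhenotypeTable

__all__ = ["impute_missing", "rrblup_solve", "choose_lambda"]


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage by the marker's mean over non-missing lines."""
    dosage = geno.dosage.copy()
    miss = np.isnan(dosage)
    if not miss.any():
        return geno
    fully_missing = miss.all(axis=0)
    if fully_missing.any():
        bad = [geno.marker_names[j] for j in np.flatnonzero(fully_missing)]
        raise ValueError(f"markers with no observed calls (filter them first): {bad}")
    col_means = np.nanmean(dosage, axis=0)
    dosage[miss] = np.broadcast_to(col_means, dosage.shape)[miss]
    out = GenotypeMatrix.__new__(GenotypeMatrix)  # bypass {0,1,2} check: means are fractional
    out.line_ids = list(geno.line_ids)
    out.marker_names = list(geno.marker_names)
    out.dosage = dosage
    return out


def _aligned_design(geno: GenotypeMatrix, pheno: PhenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Return (Z, y) for the phenotyped lines, in phenotype order."""
    y_lines = pheno.line_ids
    geno_index = {l: i for i, l in enumerate(geno.line_ids)}
    missing = [l for l in y_lines if l not in geno_index]
    if missing:
        raise ValueError(f"phenotyped lines without genotypes: {missing}")
    rows = [geno_index[l] for l in y_lines]
    Z = geno.dosage[rows]
    if np.isnan(Z).any():
        raise ValueError("genotypes contain missing dosages; run impute_missing first")
    return Z, pheno.values


def rrblup_solve(geno: GenotypeMatrix, pheno: PhenotypeTable, lam: float) -> MarkerEffects:
    """Solve the mixed-model equations for the intercept and marker effects."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    Z, y = _aligned_design(geno, pheno)
    n, m = Z.shape
    if n < 2:
        raise ValueError("need at least 2 training lines")
    if m <= n:
        beta0, u = _solve_primal(Z, y, lam)
    else:
        beta0, u = _solve_dual(Z, y, lam)
    return MarkerEffects(
        intercept=float(beta0),
        effects=pd.Series(u, index=geno.marker_names),
        lambda_used=float(lam),
    )


def _solve_primal(Z: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    n, m = Z.shape
    A = np.empty((m + 1, m + 1))
    A[0, 0] = n
    A[0, 1:] = Z.sum(axis=0)
    A[1:, 0] = A[0, 1:]
    A[1:, 1:] = Z.T @ Z + lam * np.eye(m)
    rhs = np.concatenate(([y.sum()], Z.T @ y))
    try:
        sol = linalg.solve(A, rhs, assume_a="pos")
    except linalg.LinAlgError as exc:  # pragma: no cover - lam>0 keeps A pd
        raise linalg.LinAlgError(f"singular mixed-model system: {exc}") from exc
    return sol[0], sol[1:]


def _solve_dual(Z: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """Kernel form: center out the intercept, solve n x n instead of m x m."""
    zbar = Z.mean(axis=0)
    Zc = Z - zbar
    yc = y - y.mean()
    K = Zc @ Zc.T
    alpha = linalg.solve(K + lam * np.eye(len(y)), yc, assume_a="pos")
    u = Zc.T @ alpha
    beta0 = y.mean() - zbar @ u
    return beta0, u


def _reml_spectrum(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-spectrum of the intercept-projected kernel and projected data.

    Projects onto the (n-1)-dim space orthogonal to the intercept, then
    diagonalizes T Z Z' T' there; REML reduces to a 1-D problem in lambda.
    """
    n = len(y)
    # orthonormal basis of the complement of span(1): last n-1 columns of Q
    Q, _ = np.linalg.qr(np.ones((n, 1)), mode="complete")
    T = Q[:, 1:].T
    ZT = T @ Z
    theta, V = linalg.eigh(ZT @ ZT.T)
    eta = V.T @ (T @ y)
    return np.clip(theta, 0.0, None), eta


def _neg_reml_loglik(log_lam: float, theta: np.ndarray, eta: np.ndarray) -> float:
    lam = np.exp(log_lam)
    w = theta + lam
    n1 = len(theta)
    # profile REML deviance for y* ~ N(0, s_u^2 (theta + lambda) diag), up to constants
    return float(np.sum(np.log(w)) + n1 * np.log(np.sum(eta**2 / w)))


def choose_lambda(geno: GenotypeMatrix, pheno: PhenotypeTable, policy) -> float:
    """Resolve the shrinkage parameter.

    policy {"fixed": value} returns the value; {"reml"} (or the string
    "reml") maximizes the restricted likelihood of the equivalent
    random-effect model over log lambda in [-10, 10] and returns
    lambda = s_e^2 / s_u^2 at the optimum.
    """
    if isinstance(policy, dict) and "fixed" in policy:
        lam = float(policy["fixed"])
        if lam <= 0:
            raise ValueError("fixed lambda must be > 0")
        return lam
    if policy == "reml" or policy == {"reml"} or (isinstance(policy, dict) and "reml" in policy):
        Z, y = _aligned_design(geno, pheno)
        theta, eta = _reml_spectrum(Z, y)
        res = optimize.minimize_scalar(
            _neg_reml_loglik,
            bounds=(-10.0, 10.0),
            args=(theta, eta),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if not res.success:  # pragma: no cover - bounded Brent converges
            raise RuntimeError(f"REML did not converge on log lambda in [-10, 10]: {res.message}")
        return float(np.exp(res.x))
    raise ValueError(f"unknown lambda policy: {policy!r}")
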