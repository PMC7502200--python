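"""Parametric empirical-Bayes batch correction (ComBat).

Location/scale model: per-gene batch means and variances are estimated on
standardized data, shrunk toward across-gene priors (normal prior on the
location, inverse-gamma on the scale, hyperparameters by method of moments),
and removed.  An optional covariate design (e.g. developmental stage) is
protected: its fitted contribution is excluded from the standardization and
restored untouched.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _aprior(delta_hat: np.ndarray) -> float:
    """Inverse-gamma shape hyperparameter by method of moments across genes."""
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return float((2 * s2 + m**2) / s2)


def _bprior(delta_hat: np.ndarray) -> float:
    """Inverse-gamma scale hyperparameter by method of moments across genes."""
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return float((m * s2 + m**3) / s2)


def _it_sol(
    z: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative EB solution for one batch (genes vectorized).

    z: genes x batch-samples standardized data; gamma_hat/delta_hat per gene.
    """
    n = z.shape[1]
    gamma = gamma_hat.copy()
    delta = delta_hat.copy()
    change = 1.0
    while change > conv:
        gamma_new = (n * tau2 * gamma_hat + delta * gamma_bar) / (n * tau2 + delta)
        ssq = ((z - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (0.5 * ssq + b) / (n / 2 + a - 1)
        change = max(
            np.abs(gamma_new - gamma).max() / np.abs(gamma).max(),
            np.abs(delta_new - delta).max() / np.abs(delta).max(),
        )
        gamma, delta = gamma_new, delta_new
    return gamma, delta


def combat(
    data: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Adjust a genes x samples matrix for batch.

    ``covariates``: optional samples x p numeric design of effects to protect
    (no intercept; e.g. drop-first stage dummies).  Raises on a design that
    is not full rank (batch confounded with a protected covariate).
    """
    y = data.to_numpy(dtype=float)
    batch = batch.loc[data.columns].astype(str)
    levels = sorted(batch.unique())
    if len(levels) < 2:
        return data.copy()
    z_design = np.column_stack([(batch == b).to_numpy(float) for b in levels])
    n_batches = z_design.sum(axis=0)
    if (n_batches < 2).any():
        raise ValueError("every batch needs at least 2 samples")
    n = y.shape[1]

    if covariates is not None:
        c = covariates.loc[data.columns].to_numpy(dtype=float)
        x = np.hstack([z_design, c])
    else:
        c = None
        x = z_design
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            "design is singular: a batch is confounded with a protected covariate "
            "(e.g. a library used for a single stage)"
        )

    # per-gene OLS fit; pooled variance of full-model residuals
    beta = np.linalg.solve(x.T @ x, x.T @ y.T)  # (B+p) x genes
    grand_mean = (n_batches / n) @ beta[: len(levels)]
    resid = y.T - x @ beta
    var_pooled = (resid**2).mean(axis=0)
    var_pooled = np.where(var_pooled == 0, 1e-12, var_pooled)

    stand_mean = np.tile(grand_mean, (n, 1))
    if c is not None:
        stand_mean = stand_mean + c @ beta[len(levels):]
    s_data = (y.T - stand_mean) / np.sqrt(var_pooled)  # samples x genes

    # EB shrinkage of per-batch location/scale
    bayes = s_data.copy()
    for bi, level in enumerate(levels):
        idx = (batch == level).to_numpy()
        zb = s_data[idx].T  # genes x nb
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        a = _aprior(delta_hat)
        b = _bprior(delta_hat)
        gamma_star, delta_star = _it_sol(zb, gamma_hat, delta_hat, gamma_bar, tau2, a, b)
        bayes[idx] = (zb - gamma_star[:, None]).T / np.sqrt(delta_star)[None, :]

    out = bayes * np.sqrt(var_pooled) + stand_mean
    return pd.DataFrame(out.T, index=data.index, columns=data.columns)
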