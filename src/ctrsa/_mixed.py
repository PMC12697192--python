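"""Shared helpers for the mixed-model fits."""

from __future__ import annotations

import warnings

import numpy as np


def fit_mixedlm_reml(model):
    """REML-fit a statsmodels MixedLM, tolerating boundary solutions.

    Variance components at or near the zero boundary make the REML
    Hessian singular: gradient-based optimizers can step into degenerate
    corners of the variance space (raising LinAlgError mid line-search)
    and the boundary solution triggers convergence warnings even though
    the estimate itself is valid. Retries with derivative-free
    optimizers on hard failures; warnings are suppressed and the
    convergence status is preserved on the result.
    """
    last_error = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "powell", "nm"):
            try:
                if method is None:
                    return model.fit(reml=True)
                return model.fit(reml=True, method=method, maxiter=2000)
            except np.linalg.LinAlgError as exc:
                last_error = exc
    raise last_error


def fixed_effects_covariance(
    fit, X: np.ndarray, Z: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Model-based covariance of the fixed effects at the estimated
    variance components: inv(sum_i X_i' V_i^-1 X_i) with
    V_i = sigma^2 I + Z_i G Z_i'.

    Works also when the REML Hessian is singular (variance on the
    boundary), where the joint covariance of all parameters is not
    available.
    """
    X = np.asarray(X, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.ndim == 1:
        Z = Z[:, None]
    # exactly-interpolated (noiseless) data gives sigma2 = 0; floor it so
    # V_i stays invertible — the betas are exact there and SEs ~ 0
    sigma2 = max(float(fit.scale), 1e-12)
    G = np.atleast_2d(np.asarray(fit.cov_re, dtype=float))
    A = np.zeros((X.shape[1], X.shape[1]))
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        Xi = X[idx]
        Zi = Z[idx]
        Vi = sigma2 * np.eye(len(idx)) + Zi @ G @ Zi.T
        A += Xi.T @ np.linalg.solve(Vi, Xi)
    return np.linalg.inv(A)
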