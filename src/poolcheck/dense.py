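"""Dense-matrix restricted-likelihood evaluation, used as a cross-check.

These routines build the full m x m (univariate) or 2m x 2m (bivariate)
marginal covariance explicitly and evaluate the restricted log-likelihood by
generic linear algebra.  They share no code with the fast contrast-space
path in :mod:`poolcheck.reml` / :mod:`poolcheck.pairs` and exist so that the
fast path can be verified against straightforward algebra on small problems;
they are O(m³) and not meant for production fits.

Constant convention: the error-contrast form for an orthonormal complement
basis of the fixed-effect column space,

    l_R = -1/2 [ (m-p) log 2π + log|V| + log|XᵀV⁻¹X| - log|XᵀX| + rᵀV⁻¹r ],

with r the GLS residual, which is identical to the contrast-space value.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dense_reml_loglik", "dense_bivariate_reml_loglik"]

_LOG2PI = np.log(2.0 * np.pi)


def _reml_core(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign2, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign2 <= 0:
        return -np.inf
    _, logdetXtX = np.linalg.slogdet(X.T @ X)
    beta = np.linalg.solve(XtViX, X.T @ (Vi @ y))
    r = y - X @ beta
    quad = float(r @ (Vi @ r))
    p = X.shape[1]
    val = (len(y) - p) * _LOG2PI + logdetV + logdetXtViX - logdetXtX + quad
    return -0.5 * val


def dense_reml_loglik(X: np.ndarray, Z: np.ndarray, y: np.ndarray,
                      sigma_u2: float, sigma_e2: float) -> float:
    """Univariate restricted log-likelihood with V = σ_u² ZZᵀ + σ_e² I."""
    m = Z.shape[0]
    V = sigma_u2 * (Z @ Z.T) + sigma_e2 * np.eye(m)
    return _reml_core(np.asarray(y, float), X, V)


def dense_bivariate_reml_loglik(
    X: np.ndarray, Z: np.ndarray, y_j: np.ndarray, y_k: np.ndarray,
    sigma_u2_j: float, sigma_u2_k: float, r_u: float,
    sigma_e2_j: float, sigma_e2_k: float, r_e: float = 0.0,
) -> float:
    """Bivariate restricted log-likelihood for two pools sharing X and Z.

    Animal effects for the two pools are correlated ``r_u`` within animal and
    independent across animals; residuals are paired per SNP with correlation
    ``r_e``.
    """
    m = Z.shape[0]
    ZZt = Z @ Z.T
    eye = np.eye(m)
    cu = r_u * np.sqrt(sigma_u2_j * sigma_u2_k)
    ce = r_e * np.sqrt(sigma_e2_j * sigma_e2_k)
    V = np.block([
        [sigma_u2_j * ZZt + sigma_e2_j * eye, cu * ZZt + ce * eye],
        [cu * ZZt + ce * eye, sigma_u2_k * ZZt + sigma_e2_k * eye],
    ])
    Xs = np.kron(np.eye(2), X)
    y = np.concatenate([np.asarray(y_j, float), np.asarray(y_k, float)])
    return _reml_core(y, Xs, V)
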