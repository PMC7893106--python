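"""Bivariate REML: correlation of animal contributions between two pools.

Two pools built from the same animals share the genotype design Z, so the
stacked model for their frequency vectors is

    [y_j; y_k] = (I₂⊗X) β + (I₂⊗Z) [u_j; u_k] + [e_j; e_k],

with Cov(u_ji, u_ki) = r_u σ_u,j σ_u,k within each animal (animals
independent) and residuals paired per SNP with optional correlation r_e.
The shared Z means one contrast-space decomposition block-diagonalizes the
whole 2m x 2m covariance into independent 2x2 blocks

    V_s = λ_s Σ_u + Σ_e

over the singular directions (λ_s = 0 off the genotype contrast), so each
likelihood evaluation is O(rank).  Parameters are optimized on transformed
coordinates — log variances, atanh correlations — by bounded L-BFGS-B
starting from the two univariate fits, per the protocol of fitting pools
two at a time with univariate starting values.  Fits with |r̂_u| at the
correlation bound are flagged as boundary fits.

A residual cross-pool correlation is estimated by default: two array
measurements of the same SNP can share technical artifacts, and the random
effect remains identifiable against it because only the former is modulated
by the spectrum of Z.  It can be fixed at zero by a switch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .io import AlignedDataset, PoolDataError
from .reml import ContributionFit, ContrastWorkspace, fit_univariate, get_workspace

__all__ = ["PairCorrelationFit", "PairGrid", "fit_bivariate", "fit_all_pairs"]

_LOG2PI = np.log(2.0 * np.pi)
_ATANH_BOUND = 8.0  # |r| <= tanh(8) ~ 1 - 2e-7
_VAR_LOG_BOUNDS = (-46.0, 10.0)
_R_BOUNDARY = 0.999


@dataclass
class PairCorrelationFit:
    """Bivariate REML result for one unordered pool pair."""

    pool_j: str
    pool_k: str
    sigma_u_j: float
    sigma_u_k: float
    r_u: float
    sigma_e_j: float
    sigma_e_k: float
    r_e: float
    loglik: float
    loglik_start: float
    converged: bool
    boundary: bool
    n_iter: int
    start: dict[str, float] = field(default_factory=dict)


def _neg2_restricted(theta: np.ndarray, lam: np.ndarray,
                     tj: np.ndarray, tk: np.ndarray,
                     s0: np.ndarray, n0: int, m_eff: int,
                     estimate_re: bool) -> float:
    """-2 x restricted loglik on transformed parameters.

    theta = [log σ_u,j², log σ_u,k², atanh r_u, log σ_e,j², log σ_e,k²
             (, atanh r_e)].  s0 is the 2x2 cross-product matrix of the
    projected y's outside the genotype contrast; n0 its dimension count.
    """
    vuj, vuk = np.exp(theta[0]), np.exp(theta[1])
    ru = np.tanh(theta[2])
    vej, vek = np.exp(theta[3]), np.exp(theta[4])
    re = np.tanh(theta[5]) if estimate_re else 0.0
    cu = ru * np.sqrt(vuj * vuk)
    ce = re * np.sqrt(vej * vek)

    a = lam * vuj + vej
    b = lam * cu + ce
    d = lam * vuk + vek
    det = a * d - b * b
    if np.any(det <= 0.0):
        return np.inf
    quad = float(((d * tj * tj - 2.0 * b * tj * tk + a * tk * tk) / det).sum())
    logdet = float(np.log(det).sum())

    det_e = vej * vek - ce * ce
    if det_e <= 0.0:
        return np.inf
    zero_quad = (vek * s0[0, 0] - 2.0 * ce * s0[0, 1] + vej * s0[1, 1]) / det_e
    val = logdet + quad + n0 * np.log(det_e) + zero_quad + 2 * m_eff * _LOG2PI
    return val


def bivariate_loglik(ws: ContrastWorkspace, y_j: np.ndarray, y_k: np.ndarray,
                     sigma_u2_j: float, sigma_u2_k: float, r_u: float,
                     sigma_e2_j: float, sigma_e2_k: float,
                     r_e: float = 0.0) -> float:
    """Fast-path bivariate restricted loglik at explicit parameter values."""
    tj, s0j = ws.transform(y_j)
    tk, s0k = ws.transform(y_k)
    s0jk = ws.cross_ssq0(y_j, y_k, tj, tk)
    s0 = np.array([[s0j, s0jk], [s0jk, s0k]])
    theta = np.array([
        np.log(sigma_u2_j), np.log(sigma_u2_k), np.arctanh(r_u),
        np.log(sigma_e2_j), np.log(sigma_e2_k), np.arctanh(r_e),
    ])
    val = _neg2_restricted(theta, ws.lam, tj, tk, s0,
                           ws.m_eff - ws.rank, ws.m_eff, True)
    return -0.5 * val


def fit_bivariate(
    data: AlignedDataset,
    pool_j: str,
    pool_k: str,
    start_j: ContributionFit | None = None,
    start_k: ContributionFit | None = None,
    estimate_residual_corr: bool = True,
    max_iter: int = 200,
) -> PairCorrelationFit:
    """Bivariate REML fit for one pool pair, started at the univariate fits.

    Raises for non-finite inputs; non-convergence is reported on the returned
    record (``converged`` False, last iterate retained), not raised.
    """
    if pool_j == pool_k:
        raise PoolDataError("bivariate fit needs two distinct pool ids")
    ws = get_workspace(data)
    y_j = data.pools.frequencies_for(pool_j)
    y_k = data.pools.frequencies_for(pool_k)
    if not (np.all(np.isfinite(y_j)) and np.all(np.isfinite(y_k))):
        raise PoolDataError(f"pair ({pool_j!r}, {pool_k!r}): non-finite frequencies")
    if start_j is None:
        start_j = fit_univariate(data, pool_j)
    if start_k is None:
        start_k = fit_univariate(data, pool_k)

    tj, s0j = ws.transform(y_j)
    tk, s0k = ws.transform(y_k)
    s0jk = ws.cross_ssq0(y_j, y_k, tj, tk)
    s0 = np.array([[s0j, s0jk], [s0jk, s0k]])
    n0 = ws.m_eff - ws.rank

    def logv(sigma: float, fallback: float) -> float:
        v = sigma * sigma
        return float(np.log(max(v, fallback)))

    # variance floors keep log-scale starts finite for boundary univariate fits
    ve_floor = 1e-14
    vu_floor = max(1e-6 * (start_j.sigma_e**2 + start_k.sigma_e**2), 1e-14)
    start = {
        "sigma_u_j": start_j.sigma_u, "sigma_u_k": start_k.sigma_u,
        "r_u": 0.0,
        "sigma_e_j": start_j.sigma_e, "sigma_e_k": start_k.sigma_e,
        "r_e": 0.0,
    }
    theta0 = [
        logv(start_j.sigma_u, vu_floor), logv(start_k.sigma_u, vu_floor), 0.0,
        logv(start_j.sigma_e, ve_floor), logv(start_k.sigma_e, ve_floor),
    ]
    if estimate_residual_corr:
        theta0.append(0.0)
    theta0 = np.asarray(theta0)

    args = (ws.lam, tj, tk, s0, n0, ws.m_eff, estimate_residual_corr)
    f0 = _neg2_restricted(theta0, *args)
    bounds = [_VAR_LOG_BOUNDS, _VAR_LOG_BOUNDS, (-_ATANH_BOUND, _ATANH_BOUND),
              _VAR_LOG_BOUNDS, _VAR_LOG_BOUNDS]
    if estimate_residual_corr:
        bounds.append((-_ATANH_BOUND, _ATANH_BOUND))
    res = minimize(_neg2_restricted, theta0, args=args, method="L-BFGS-B",
                   bounds=bounds,
                   options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9})
    theta = res.x if res.fun <= f0 else theta0
    fval = min(float(res.fun), f0)

    vuj, vuk = np.exp(theta[0]), np.exp(theta[1])
    ru = float(np.tanh(theta[2]))
    vej, vek = np.exp(theta[3]), np.exp(theta[4])
    re = float(np.tanh(theta[5])) if estimate_residual_corr else 0.0
    boundary = abs(ru) >= _R_BOUNDARY
    return PairCorrelationFit(
        pool_j=pool_j, pool_k=pool_k,
        sigma_u_j=float(np.sqrt(vuj)), sigma_u_k=float(np.sqrt(vuk)), r_u=ru,
        sigma_e_j=float(np.sqrt(vej)), sigma_e_k=float(np.sqrt(vek)), r_e=re,
        loglik=-0.5 * fval, loglik_start=-0.5 * f0,
        converged=bool(res.success), boundary=boundary,
        n_iter=int(res.nit), start=start,
    )


@dataclass
class PairGrid:
    """All unordered pool pairs with their bivariate fits (or failure records)."""

    pool_ids: list[str]
    fits: dict[tuple[str, str], PairCorrelationFit]
    failures: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.fits) + len(self.failures)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (j, k), f in self.fits.items():
            rows.append({
                "pool_j": j, "pool_k": k, "r_u": f.r_u,
                "sd_u_j": f.sigma_u_j, "sd_u_k": f.sigma_u_k,
                "sd_e_j": f.sigma_e_j, "sd_e_k": f.sigma_e_k,
                "r_e": f.r_e, "loglik": f.loglik, "converged": f.converged,
            })
        for (j, k), msg in self.failures.items():
            rows.append({"pool_j": j, "pool_k": k, "r_u": np.nan,
                         "sd_u_j": np.nan, "sd_u_k": np.nan, "sd_e_j": np.nan,
                         "sd_e_k": np.nan, "r_e": np.nan, "loglik": np.nan,
                         "converged": False})
        return pd.DataFrame(rows)


def fit_all_pairs(
    data: AlignedDataset,
    pool_ids: Sequence[str] | None = None,
    univariate_fits: Mapping[str, ContributionFit] | None = None,
    estimate_residual_corr: bool = True,
) -> PairGrid:
    """Bivariate fits for every unordered pair of the given pools.

    Fitting is deterministic given the data; per-pair exceptions are recorded
    as failures rather than aborting the grid.  P pools yield P(P−1)/2 pairs.
    """
    if pool_ids is None:
        pool_ids = list(data.pools.pool_ids)
    pool_ids = list(pool_ids)
    if len(pool_ids) < 2:
        raise PoolDataError("need at least 2 pools for pairwise analysis")
    if univariate_fits is None:
        univariate_fits = {pid: fit_univariate(data, pid) for pid in pool_ids}
    fits: dict[tuple[str, str], PairCorrelationFit] = {}
    failures: dict[tuple[str, str], str] = {}
    for j, k in itertools.combinations(pool_ids, 2):
        try:
            fits[(j, k)] = fit_bivariate(
                data, j, k, univariate_fits[j], univariate_fits[k],
                estimate_residual_corr=estimate_residual_corr,
            )
        except Exception as exc:  # noqa: BLE001 - degrade gracefully per pair
            failures[(j, k)] = f"{type(exc).__name__}: {exc}"
    return PairGrid(pool_ids, fits, failures)
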