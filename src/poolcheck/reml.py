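"""Univariate REML for the animal-contribution model of one pool.

Model.  For pool j with measured allele frequencies ``y_s`` over m SNPs and
n genotyped animals with covariates ``g_is = dosage_is / 2``,

    y_s = β0 + β1 ḡ_s + Σ_i u_i g_is + e_s,
    u_i ~ N(0, σ_u²) iid,   e_s ~ N(0, σ_e²),

where ḡ_s is the per-SNP mean of the g's.  Under exactly equal contributions
E[y_s] = ḡ_s, so with the fixed regression on ḡ_s present the random
coefficients u_i are interpretable as each animal's contribution deviation
from 1/n; their SD σ_u (the "animal contribution SD") measures pooling
accuracy, and their BLUPs expose overrepresented (contaminating) animals.

Computation.  With X = [1, ḡ] and Z the m x n matrix of g_is, the marginal
covariance is V = σ_u² Z Zᵀ + σ_e² I.  We work in the error-contrast space:
project X out of both y and Z, take one thin SVD of the projected Z, and the
restricted likelihood separates over the singular directions.  REML then
profiles down to a one-dimensional optimization over the variance ratio
γ = σ_u²/σ_e², solved by a coarse log-grid pass plus bounded Brent
refinement; γ̂ = 0 boundary solutions are reported, not errored.

Note Z·1 = n ḡ lies in the column space of X, so the projected Z has rank at
most n−1 and the fitted BLUPs satisfy Σ_i û_i = 0 exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .io import AlignedDataset, PoolDataError

__all__ = [
    "ContrastWorkspace",
    "ContributionFit",
    "OverrepresentationReport",
    "PoolFilterResult",
    "get_workspace",
    "fit_univariate",
    "blup_contributions",
    "filter_contaminated_pools",
]

_LOG2PI = np.log(2.0 * np.pi)

#: profile-REML search bounds on the variance ratio sigma_u^2 / sigma_e^2
RATIO_BOUNDS = (1e-10, 1e6)


class ContrastWorkspace:
    """Error-contrast decomposition shared by all pools of one aligned dataset.

    Holds the QR basis of X = [1, ḡ], the thin SVD of the X-projected
    genotype design Z, and transforms of pool frequency vectors into
    (singular-direction coordinates, leftover residual sum of squares).
    Building it costs one SVD of an m x n matrix; every subsequent
    likelihood evaluation is O(rank).
    """

    def __init__(self, g: np.ndarray, gbar: np.ndarray | None = None):
        Z = np.ascontiguousarray(g.T, dtype=float)  # (m, n)
        if np.isnan(Z).any():
            raise PoolDataError("workspace requires complete genotypes (no NaN)")
        m, n = Z.shape
        if gbar is None:
            gbar = Z.mean(axis=1)
        X = np.column_stack([np.ones(m), np.asarray(gbar, dtype=float)])
        # guard against a constant gbar column (all SNPs monomorphic at same value)
        if np.ptp(X[:, 1]) < 1e-14:
            X = X[:, :1]
        Q, _ = np.linalg.qr(X)
        Zp = Z - Q @ (Q.T @ Z)
        U, s, _ = np.linalg.svd(Zp, full_matrices=False)
        keep = s > (s[0] * 1e-10 if s.size and s[0] > 0 else np.inf)
        self.X = X
        self.Q = Q
        self.Z = Z
        self.U = np.ascontiguousarray(U[:, keep])
        self.lam = s[keep] ** 2
        self.m = m
        self.n = n
        self.p = X.shape[1]
        self.m_eff = m - self.p
        self.rank = int(keep.sum())

    def transform(self, y: np.ndarray) -> tuple[np.ndarray, float]:
        """Return (t, ssq0): coordinates of the X-projected y on the singular
        directions of Z, and the squared norm left outside them."""
        y = np.asarray(y, dtype=float)
        y_perp = y - self.Q @ (self.Q.T @ y)
        t = self.U.T @ y_perp
        ssq0 = float(max(y_perp @ y_perp - t @ t, 0.0))
        return t, ssq0

    def cross_ssq0(self, yj: np.ndarray, yk: np.ndarray,
                   tj: np.ndarray, tk: np.ndarray) -> float:
        """Cross-product of two projected y's outside the singular directions."""
        yj_p = yj - self.Q @ (self.Q.T @ yj)
        yk_p = yk - self.Q @ (self.Q.T @ yk)
        return float(yj_p @ yk_p - tj @ tk)

    # -- likelihood ---------------------------------------------------------

    def loglik(self, y: np.ndarray, sigma_u2: float, sigma_e2: float) -> float:
        """Restricted log-likelihood at (σ_u², σ_e²), error-contrast convention."""
        t, ssq0 = self.transform(y)
        return self.loglik_from_parts(t, ssq0, sigma_u2, sigma_e2)

    def loglik_from_parts(self, t: np.ndarray, ssq0: float,
                          sigma_u2: float, sigma_e2: float) -> float:
        d = sigma_e2 + sigma_u2 * self.lam
        n0 = self.m_eff - self.rank
        val = (
            self.m_eff * _LOG2PI
            + np.log(d).sum() + n0 * np.log(sigma_e2)
            + (t * t / d).sum() + ssq0 / sigma_e2
        )
        return -0.5 * val

    # -- GLS fixed effects and BLUPs ---------------------------------------

    def beta_blup(self, y: np.ndarray, sigma_u2: float,
                  sigma_e2: float) -> tuple[np.ndarray, np.ndarray]:
        """GLS fixed effects and random-coefficient BLUPs at given components.

        û = σ_u² Zᵀ V⁻¹ (y − X β̂) with V = σ_u² Z Zᵀ + σ_e² I, evaluated via
        the Woodbury identity on the n x n system.
        """
        Z, X = self.Z, self.X
        if sigma_e2 <= 0:
            # degenerate noiseless case: OLS beta, zero BLUPs
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return beta, np.zeros(self.n)
        if sigma_u2 <= 0:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return beta, np.zeros(self.n)
        C = Z.T @ Z + (sigma_e2 / sigma_u2) * np.eye(self.n)
        cf = cho_factor(C)

        def vinv(M: np.ndarray) -> np.ndarray:
            return (M - Z @ cho_solve(cf, Z.T @ M)) / sigma_e2

        ViX = vinv(X)
        Viy = vinv(y)
        beta = np.linalg.solve(X.T @ ViX, X.T @ Viy)
        resid = y - X @ beta
        u = sigma_u2 * (Z.T @ vinv(resid))
        return beta, u


def get_workspace(data: AlignedDataset) -> ContrastWorkspace:
    """Workspace for an aligned dataset, cached on the dataset object."""
    if data._workspace is None:
        data._workspace = ContrastWorkspace(data.genotypes.g)
    return data._workspace


@dataclass
class ContributionFit:
    """Univariate REML result for one pool."""

    pool_id: str
    sigma_u: float
    sigma_e: float
    beta: np.ndarray
    blups: np.ndarray
    loglik: float
    converged: bool
    boundary: bool
    n_animals: int
    n_snps: int
    n_iter: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def variance_ratio(self) -> float:
        return (self.sigma_u / self.sigma_e) ** 2 if self.sigma_e > 0 else np.inf


def fit_univariate(
    data: AlignedDataset,
    pool_id: str,
    ratio_bounds: tuple[float, float] = RATIO_BOUNDS,
    xatol: float = 1e-10,
    grid_points: int = 61,
) -> ContributionFit:
    """Profile-REML fit of the contribution model for one pool.

    Requires at least ``n_animals + 2`` SNPs; attaches a low-information
    warning when the contrast dimension does not exceed the number of
    animals.  Returns boundary fits (σ̂_u = 0) rather than raising.
    """
    ws = get_workspace(data)
    y = data.pools.frequencies_for(pool_id)
    if not np.all(np.isfinite(y)):
        raise PoolDataError(f"pool {pool_id!r}: non-finite frequencies")
    n, m = ws.n, ws.m
    if m < n + 2:
        raise PoolDataError(
            f"pool {pool_id!r}: {m} SNPs is fewer than n_animals + 2 = {n + 2}"
        )
    fit_warnings: list[str] = []
    if ws.m_eff <= n:
        fit_warnings.append(
            f"low information: contrast dimension {ws.m_eff} <= {n} animals"
        )

    t, ssq0 = ws.transform(y)
    m_eff, lam, rank = ws.m_eff, ws.lam, ws.rank
    tt = t * t

    def profile_neg2(gamma: float) -> tuple[float, float]:
        """Profiled -2 restricted loglik and the profiled sigma_e^2."""
        d = 1.0 + gamma * lam
        rss = float((tt / d).sum() + ssq0)
        if rss <= 0.0:
            return -np.inf, 0.0
        se2 = rss / m_eff
        val = m_eff * (np.log(se2) + 1.0 + _LOG2PI) + float(np.log(d).sum())
        return val, se2

    # degenerate: y exactly in the fixed-effect space (no residual at all)
    total_rss = float(tt.sum() + ssq0)
    if total_rss <= max(1e-30, 1e-18 * m_eff):
        beta, _ = ws.beta_blup(y, 0.0, 0.0)
        fit_warnings.append("degenerate fit: zero residual variation")
        return ContributionFit(pool_id, 0.0, 0.0, beta, np.zeros(n), np.inf,
                               True, True, n, m, 0, fit_warnings)

    lo, hi = np.log(ratio_bounds[0]), np.log(ratio_bounds[1])
    grid = np.linspace(lo, hi, grid_points)
    vals = np.array([profile_neg2(np.exp(x))[0] for x in grid])
    best = int(np.argmin(vals))
    lo_b = grid[max(best - 1, 0)]
    hi_b = grid[min(best + 1, grid_points - 1)]
    res = minimize_scalar(lambda x: profile_neg2(np.exp(x))[0],
                          bounds=(lo_b, hi_b), method="bounded",
                          options={"xatol": xatol})
    gamma_hat = float(np.exp(res.x))
    val_hat, se2_hat = profile_neg2(gamma_hat)
    val_zero, se2_zero = profile_neg2(0.0)

    boundary = False
    if val_zero <= val_hat or gamma_hat <= ratio_bounds[0] * (1 + 1e-6):
        gamma_hat, val_hat, se2_hat = 0.0, val_zero, se2_zero
        boundary = True
    elif gamma_hat >= ratio_bounds[1] * (1 - 1e-6):
        boundary = True
        fit_warnings.append("variance ratio at upper search bound")

    su2 = gamma_hat * se2_hat
    beta, u = ws.beta_blup(y, su2, se2_hat)
    return ContributionFit(
        pool_id=pool_id,
        sigma_u=float(np.sqrt(su2)),
        sigma_e=float(np.sqrt(se2_hat)),
        beta=beta,
        blups=u,
        loglik=-0.5 * val_hat,
        converged=True,
        boundary=boundary,
        n_animals=n,
        n_snps=m,
        n_iter=int(getattr(res, "nfev", 0)) + grid_points,
        warnings=fit_warnings,
    )


@dataclass
class OverrepresentationReport:
    """Per-animal BLUPs, standardized scores and contamination flags for one pool."""

    pool_id: str
    animal_ids: list[str]
    blups: np.ndarray
    scores: np.ndarray
    flags: np.ndarray
    threshold: float
    estimated_weights: np.ndarray
    note: str = ""

    @property
    def flagged_animals(self) -> list[str]:
        return [a for a, f in zip(self.animal_ids, self.flags) if f]


def blup_contributions(fit: ContributionFit, data: AlignedDataset,
                       threshold: float = 3.0) -> OverrepresentationReport:
    """Standardize the fit's BLUPs and flag overrepresented animals.

    Each animal's estimated pool weight is ``1/n + û_i``; the flag rule is
    one-sided, ``û_i / σ̂_u > threshold`` (overrepresentation only, since
    cross-contamination inflates specific animals' weights).  A σ̂_u = 0
    boundary fit yields all-zero scores and no flags.
    """
    n = fit.n_animals
    weights = 1.0 / n + fit.blups
    if fit.sigma_u <= 0:
        return OverrepresentationReport(
            fit.pool_id, list(data.genotypes.animal_ids), fit.blups,
            np.zeros(n), np.zeros(n, dtype=bool), threshold, weights,
            note="sigma_u = 0 (boundary fit): standardized scores undefined, no flags",
        )
    scores = fit.blups / fit.sigma_u
    flags = scores > threshold
    return OverrepresentationReport(
        fit.pool_id, list(data.genotypes.animal_ids), fit.blups,
        scores, flags, threshold, weights,
    )


@dataclass
class PoolFilterResult:
    retained: list[str]
    excluded: dict[str, str]


def filter_contaminated_pools(
    reports: Mapping[str, OverrepresentationReport] | Sequence[OverrepresentationReport],
) -> PoolFilterResult:
    """Exclude every pool with at least one flagged animal.

    Returns the retained pool ids (input order) and, per excluded pool, a
    reason naming the flagged animals.  Warns if nothing survives.
    """
    if not isinstance(reports, Mapping):
        reports = {r.pool_id: r for r in reports}
    retained: list[str] = []
    excluded: dict[str, str] = {}
    for pid, rep in reports.items():
        flagged = rep.flagged_animals
        if flagged:
            excluded[pid] = (
                f"cross-contamination suspected: {len(flagged)} overrepresented "
                f"animal(s) ({', '.join(flagged)}) with standardized BLUP > "
                f"{rep.threshold:g}"
            )
        else:
            retained.append(pid)
    if not retained:
        warnings.warn("all pools excluded by the contamination filter")
    return PoolFilterResult(retained, excluded)
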