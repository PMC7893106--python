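"""Method comparison: does pooling method explain contribution structure?

Two tests, both operating on outputs of the pairwise bivariate fits:

* **PERMANOVA** (Anderson's permutational MANOVA, the Adonis test) on a
  distance matrix derived from the pool-pair contribution correlations,
  testing whether pools cluster by construction method.  One factor only.
  The permutation p-value is computed from label permutations of the
  distance matrix partition; when the label multiset admits few enough
  distinct assignments the full enumeration is used instead of sampling.

* **Kruskal-Wallis** rank test on one contribution SD per pool (the
  univariate estimates — one value per experimental unit, avoiding the
  pseudo-replication of the 33 bivariate estimates each pool appears in),
  grouped by method.

Also provides the descriptive within/between-method correlation and
per-method SD summaries behind the usual heatmap/boxplot figures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pairs import PairGrid
from .reml import ContributionFit

__all__ = [
    "CorrelationMatrix",
    "DistanceMatrix",
    "PermanovaResult",
    "KruskalWallisResult",
    "MethodSummary",
    "correlation_matrix_from_pairs",
    "correlation_to_distance",
    "permanova",
    "kruskal_wallis",
    "method_summary",
]


@dataclass
class CorrelationMatrix:
    """Symmetric pool x pool contribution-correlation matrix, unit diagonal."""

    pool_ids: list[str]
    values: np.ndarray
    methods: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        P = len(self.pool_ids)
        if v.shape != (P, P):
            raise ValueError(f"correlation matrix shape {v.shape} != ({P}, {P})")
        if np.abs(v - v.T).max(initial=0.0) > 1e-8:
            raise ValueError("correlation matrix is not symmetric")
        if np.abs(np.diag(v) - 1.0).max(initial=0.0) > 1e-8:
            raise ValueError("correlation matrix diagonal must be 1")
        if np.nanmax(np.abs(v), initial=0.0) > 1.0 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pool_ids, columns=self.pool_ids)


@dataclass
class DistanceMatrix:
    """Symmetric pool x pool distances with zero diagonal."""

    pool_ids: list[str]
    values: np.ndarray
    methods: list[str]
    transform: str = "one_minus_r"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.abs(v - v.T).max(initial=0.0) > 1e-8:
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal must be 0")
        self.values = 0.5 * (v + v.T)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pool_ids, columns=self.pool_ids)


def correlation_matrix_from_pairs(
    grid: PairGrid, methods: Mapping[str, str] | Sequence[str],
) -> CorrelationMatrix:
    """Assemble the symmetric correlation matrix from a pair grid.

    ``methods`` maps pool id -> method (or lists methods in pool order).
    A failed pair's correlation is imputed from the mean of successful
    correlations in the same method-pair class (within-method or the specific
    between-method combination), with a warning; this keeps a single failed
    fit from invalidating the whole distance matrix.
    """
    ids = list(grid.pool_ids)
    pos = {p: i for i, p in enumerate(ids)}
    if not isinstance(methods, Mapping):
        methods = dict(zip(ids, methods))
    meth = [methods[p] for p in ids]
    P = len(ids)
    M = np.full((P, P), np.nan)
    np.fill_diagonal(M, 1.0)
    for (j, k), f in grid.fits.items():
        M[pos[j], pos[k]] = M[pos[k], pos[j]] = f.r_u
    if grid.failures:
        classes: dict[frozenset, list[float]] = {}
        for (j, k), f in grid.fits.items():
            classes.setdefault(frozenset((methods[j], methods[k])), []).append(f.r_u)
        overall = [f.r_u for f in grid.fits.values()]
        for (j, k) in grid.failures:
            cls = frozenset((methods[j], methods[k]))
            pool = classes.get(cls) or overall
            if not pool:
                raise ValueError("cannot impute: no successful pair fits at all")
            M[pos[j], pos[k]] = M[pos[k], pos[j]] = float(np.mean(pool))
        warnings.warn(
            f"imputed {len(grid.failures)} failed pair correlation(s) from "
            "method-class means"
        )
    return CorrelationMatrix(ids, np.clip(M, -1.0, 1.0), meth)


def correlation_to_distance(corr: CorrelationMatrix,
                            transform: str = "one_minus_r") -> DistanceMatrix:
    """Map correlations to distances: ``1 - r`` (default) or the
    Euclidean-embeddable ``sqrt(2(1 - r))``."""
    r = corr.values
    if transform == "one_minus_r":
        d = 1.0 - r
    elif transform == "sqrt_two_one_minus_r":
        d = np.sqrt(np.clip(2.0 * (1.0 - r), 0.0, None))
    else:
        raise ValueError(f"unknown distance transform {transform!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(corr.pool_ids), d, list(corr.methods), transform)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    f: float
    r2: float
    p: float
    n_perm: int
    method: str  # "exhaustive" or "monte_carlo"
    group_sizes: dict[str, int]
    seed: int | None = None
    warning: str = ""


def _ssw_batch(D2: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Within-group sum of squared distances / group size, summed over groups,
    for a batch of label vectors (B, P)."""
    out = np.zeros(labels.shape[0])
    for lab in np.unique(labels):
        Mk = (labels == lab).astype(float).T  # (P, B)
        ng = Mk.sum(axis=0)
        vals = np.einsum("pb,pq,qb->b", Mk, D2, Mk) / (2.0 * ng)
        out += vals
    return out


def _multiset_permutations(items: list):
    """Yield the distinct permutations of a list with repeated elements."""
    counts = {}
    for x in items:
        counts[x] = counts.get(x, 0) + 1
    keys = sorted(counts)
    n = len(items)
    perm: list = [None] * n

    def rec(depth: int):
        if depth == n:
            yield list(perm)
            return
        for key in keys:
            if counts[key] > 0:
                counts[key] -= 1
                perm[depth] = key
                yield from rec(depth + 1)
                counts[key] += 1

    yield from rec(0)


def _n_distinct_assignments(sizes: Sequence[int]) -> int:
    total = math.factorial(sum(sizes))
    for s in sizes:
        total //= math.factorial(s)
    return total


def permanova(
    dist: DistanceMatrix,
    grouping: Sequence[str] | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    exhaustive: str | bool = "auto",
    exhaustive_limit: int = 100_000,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    The pseudo-F statistic partitions the total sum of squared distances
    (SS_T = Σ_{i<j} d²_ij / N) into within-group (SS_W, from within-group
    pairwise distances) and among-group (SS_A = SS_T − SS_W) components:

        F = (SS_A / (a − 1)) / (SS_W / (N − a)).

    Monte-Carlo p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm); in exhaustive
    mode every distinct assignment of labels to positions is evaluated and
    p = #{F ≥ F_obs} / #assignments (the identity included).  Exhaustive mode
    is selected automatically when that count is at most ``exhaustive_limit``.
    """
    if grouping is None:
        grouping = dist.methods
    labels = np.asarray([str(g) for g in grouping])
    P = len(dist.pool_ids)
    if labels.shape[0] != P:
        raise ValueError("grouping length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if counts.min() < 1 or P - a < 1:
        raise ValueError("each group needs >= 1 member and residual df >= 1")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    D2 = dist.values ** 2
    sst = float(D2.sum()) / (2.0 * P)
    ssw_obs = float(_ssw_batch(D2, labels[None, :])[0])
    warning = ""
    if sst <= 1e-12:
        warning = "constant distance matrix: pseudo-F undefined, p = 1"
        return PermanovaResult(0.0, 0.0, 1.0, 0, "degenerate",
                               {str(u): int(c) for u, c in zip(uniq, counts)}, None, warning)
    ssa = max(sst - ssw_obs, 0.0)

    def f_from_ssw(ssw: np.ndarray) -> np.ndarray:
        ssa_ = np.maximum(sst - ssw, 0.0)
        with np.errstate(divide="ignore"):
            return (ssa_ / (a - 1)) / (ssw / (P - a))

    f_obs = float(f_from_ssw(np.array([ssw_obs]))[0])
    r2 = ssa / sst

    n_assign = _n_distinct_assignments(counts)
    use_exhaustive = (exhaustive is True) or (exhaustive == "auto"
                                              and n_assign <= exhaustive_limit)
    if use_exhaustive:
        perms = np.array(list(_multiset_permutations(list(labels))), dtype=labels.dtype)
        f_all = f_from_ssw(_ssw_batch(D2, perms))
        p = float((f_all >= f_obs - 1e-12).sum()) / len(f_all)
        return PermanovaResult(f_obs, r2, p, len(f_all), "exhaustive",
                               {str(u): int(c) for u, c in zip(uniq, counts)}, None, warning)

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, P), dtype=labels.dtype)
    for b in range(n_perm):
        perms[b] = labels[rng.permutation(P)]
    f_perm = f_from_ssw(_ssw_batch(D2, perms))
    p = (1.0 + float((f_perm >= f_obs - 1e-12).sum())) / (1.0 + n_perm)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return PermanovaResult(f_obs, r2, p, n_perm, "monte_carlo",
                           {str(u): int(c) for u, c in zip(uniq, counts)}, seed_val, warning)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

@dataclass
class KruskalWallisResult:
    h: float
    df: int
    p: float
    group_values: dict[str, np.ndarray]
    p_perm: float | None = None
    n_perm: int = 0
    warning: str = ""


def kruskal_wallis(
    values: Sequence[float],
    grouping: Sequence[str],
    n_perm: int | None = None,
    seed: int | np.random.Generator | None = None,
) -> KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = groups − 1).

    Identical values across the board yield H = 0, p = 1 with a warning
    (the full-tie convention).  An optional permutation p-value shuffles
    values across groups.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(g) for g in grouping])
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and grouping differ in length")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if values.shape[0] < len(uniq) + 1:
        raise ValueError("too few observations for the number of groups")
    groups = {g: values[labels == g] for g in uniq}
    df = len(uniq) - 1

    if np.ptp(values) == 0.0:
        return KruskalWallisResult(0.0, df, 1.0, groups,
                                   warning="all values identical: H = 0, p = 1")
    h, p = stats.kruskal(*groups.values())
    result = KruskalWallisResult(float(h), df, float(p), groups)
    if n_perm:
        rng = np.random.default_rng(seed)
        count = 0
        vals = values.copy()
        for _ in range(n_perm):
            rng.shuffle(vals)
            hp, _ = stats.kruskal(*(vals[labels == g] for g in uniq))
            if hp >= h - 1e-12:
                count += 1
        result.p_perm = (1.0 + count) / (1.0 + n_perm)
        result.n_perm = n_perm
    return result


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------

@dataclass
class MethodSummary:
    """Plot-ready tables: correlation distributions by method pair and per-pool
    contribution-SD distributions by method."""

    correlation_summary: pd.DataFrame
    sd_summary: pd.DataFrame
    sd_by_pool: pd.DataFrame


def method_summary(
    grid: PairGrid,
    fits: Mapping[str, ContributionFit],
    methods: Mapping[str, str],
) -> MethodSummary:
    """Summaries of within-/between-method correlations and per-method SDs.

    ``correlation_summary`` has one row per unordered method pair (including
    method-with-itself = within) with count, median and quartiles of r̂;
    ``sd_summary`` one row per method over the univariate per-pool SDs.
    """
    rows = []
    by_class: dict[tuple[str, str], list[float]] = {}
    for (j, k), f in grid.fits.items():
        mj, mk = methods[j], methods[k]
        key = tuple(sorted((mj, mk)))
        by_class.setdefault(key, []).append(f.r_u)
    for (mj, mk), vals in sorted(by_class.items()):
        arr = np.asarray(vals)
        rows.append({
            "method_a": mj, "method_b": mk,
            "kind": "within" if mj == mk else "between",
            "n_pairs": len(arr),
            "median_r": float(np.median(arr)),
            "q1_r": float(np.percentile(arr, 25)),
            "q3_r": float(np.percentile(arr, 75)),
        })
    corr_df = pd.DataFrame(
        rows, columns=["method_a", "method_b", "kind", "n_pairs",
                       "median_r", "q1_r", "q3_r"])

    pool_rows = [
        {"pool_id": pid, "method": methods[pid], "sigma_u": fit.sigma_u,
         "sigma_e": fit.sigma_e}
        for pid, fit in fits.items()
    ]
    sd_by_pool = pd.DataFrame(pool_rows,
                              columns=["pool_id", "method", "sigma_u", "sigma_e"])
    sd_rows = []
    for m, sub in sd_by_pool.groupby("method", sort=True):
        arr = sub["sigma_u"].to_numpy()
        sd_rows.append({
            "method": m, "n_pools": len(arr),
            "median_sd": float(np.median(arr)),
            "q1_sd": float(np.percentile(arr, 25)),
            "q3_sd": float(np.percentile(arr, 75)),
        })
    sd_df = pd.DataFrame(sd_rows,
                         columns=["method", "n_pools", "median_sd", "q1_sd", "q3_sd"])
    return MethodSummary(corr_df, sd_df, sd_by_pool)
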