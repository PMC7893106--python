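"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's fast fitting paths: REML optima are
found by grid search plus Nelder-Mead refinement of the dense-matrix
restricted likelihood, the Kruskal-Wallis H comes from the textbook
rank-sum formula, and PERMANOVA quantities from explicit loops over pairs
and label assignments.
"""

import itertools
import math

import numpy as np
from scipy.optimize import minimize

from poolcheck.dense import dense_bivariate_reml_loglik, dense_reml_loglik


def univariate_reml_argmax(X, Z, y, grid_points=25):
    """Grid + Nelder-Mead maximization of the dense restricted likelihood
    over (sigma_u^2, sigma_e^2); returns the arg-max pair."""
    logs = np.linspace(np.log(1e-8), np.log(1.0), grid_points)

    def nll(theta):
        return -dense_reml_loglik(X, Z, y, np.exp(theta[0]), np.exp(theta[1]))

    best = min(((a, b) for a in logs for b in logs), key=lambda t: nll(t))
    res = minimize(nll, best, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    return float(np.exp(res.x[0])), float(np.exp(res.x[1])), -float(res.fun)


def bivariate_reml_argmax(X, Z, y_j, y_k, start_var_u, start_var_e,
                          r_starts=(-0.5, 0.0, 0.5, 0.9)):
    """Multi-start Nelder-Mead maximization of the dense bivariate restricted
    likelihood over (v_uj, v_uk, r_u, v_ej, v_ek), residual correlation 0."""

    def nll(theta):
        return -dense_bivariate_reml_loglik(
            X, Z, y_j, y_k, np.exp(theta[0]), np.exp(theta[1]),
            np.tanh(theta[2]), np.exp(theta[3]), np.exp(theta[4]), 0.0)

    best = None
    for r0 in r_starts:
        theta0 = [np.log(start_var_u), np.log(start_var_u), np.arctanh(r0),
                  np.log(start_var_e), np.log(start_var_e)]
        res = minimize(nll, theta0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 20000, "maxfev": 20000})
        if best is None or res.fun < best.fun:
            best = res
    th = best.x
    return (float(np.exp(th[0])), float(np.exp(th[1])), float(np.tanh(th[2])),
            float(np.exp(th[3])), float(np.exp(th[4])), -float(best.fun))


def kruskal_h_direct(groups):
    """Kruskal-Wallis H from the rank-sum formula with midrank ties and the
    standard tie-correction divisor."""
    values = np.concatenate(groups)
    n = len(values)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = values[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    h = 0.0
    start = 0
    for grp in groups:
        ni = len(grp)
        ri = ranks[start:start + ni].mean()
        h += ni * (ri - (n + 1) / 2.0) ** 2
        start += ni
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / tie


def permanova_f_direct(D, labels):
    """Pseudo-F from explicit pairwise-distance sums (no matrix tricks)."""
    labels = list(labels)
    P = len(labels)
    groups = sorted(set(labels))
    sst = sum(D[i, j] ** 2 for i in range(P) for j in range(i + 1, P)) / P
    ssw = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        ssw += sum(D[i, j] ** 2 for i, j in itertools.combinations(idx, 2)) / len(idx)
    ssa = sst - ssw
    a = len(groups)
    return (ssa / (a - 1)) / (ssw / (P - a))


def permanova_f_gower(D, labels):
    """Pseudo-F via Gower-centering: G = -1/2 J D^2 J, SS_A = tr(H G H)."""
    P = len(labels)
    J = np.eye(P) - np.ones((P, P)) / P
    G = -0.5 * J @ (D ** 2) @ J
    groups = sorted(set(labels))
    # hat matrix of the one-factor design
    Xd = np.column_stack([[1.0 if l == g else 0.0 for l in labels] for g in groups])
    H = Xd @ np.linalg.pinv(Xd.T @ Xd) @ Xd.T
    ssa = np.trace(H @ G @ H)
    sst = np.trace(G)
    ssw = sst - ssa
    a = len(groups)
    return (ssa / (a - 1)) / (ssw / (P - a))


def permanova_p_enumeration(D, labels):
    """Exact permutation p by explicit enumeration of distinct label orders."""
    f_obs = permanova_f_direct(D, labels)
    seen = set()
    count = total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if permanova_f_direct(D, list(perm)) >= f_obs - 1e-12:
            count += 1
    return count / total
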