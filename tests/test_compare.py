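"""Distance transforms, PERMANOVA, Kruskal-Wallis and method summaries."""

import numpy as np
import pytest

from poolcheck import (CorrelationMatrix, DistanceMatrix, correlation_to_distance,
                       kruskal_wallis, permanova)
from poolcheck.compare import _n_distinct_assignments

from ._oracles import (kruskal_h_direct, permanova_f_direct, permanova_f_gower,
                       permanova_p_enumeration)


def corr_matrix(values, methods=None):
    P = len(values)
    ids = [f"P{i+1}" for i in range(P)]
    return CorrelationMatrix(ids, np.asarray(values, float),
                             methods or ["M1"] * P)


def random_distance(P, rng):
    pts = rng.normal(size=(P, 3))
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    ids = [f"P{i+1}" for i in range(P)]
    return DistanceMatrix(ids, D, ["?"] * P)


class TestDistanceTransform:
    def test_endpoints_default_transform(self):
        c = corr_matrix([[1.0, 0.0, -1.0], [0.0, 1.0, 0.5], [-1.0, 0.5, 1.0]])
        d = correlation_to_distance(c)
        assert d.values[0, 1] == pytest.approx(1.0)
        assert d.values[0, 2] == pytest.approx(2.0)
        assert d.values[0, 0] == 0.0

    def test_sqrt_transform_half_correlation_gives_unit_distance(self):
        c = corr_matrix([[1.0, 0.5], [0.5, 1.0]])
        d = correlation_to_distance(c, "sqrt_two_one_minus_r")
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            CorrelationMatrix(["a", "b"], np.array([[1.0, 0.2], [0.4, 1.0]]),
                              ["M", "M"])


class TestPermanova:
    def test_perfect_separation(self):
        # all within-group distances 0, between-group 1: R^2 = 1 and the p
        # floor is the fraction of label assignments preserving the partition
        # (identity + full swap = 2 of the 20 distinct assignments)
        D = np.ones((6, 6)) - np.eye(6)
        D[:3, :3] = 0.0
        D[3:, 3:] = 0.0
        np.fill_diagonal(D, 0.0)
        dist = DistanceMatrix([f"P{i}" for i in range(6)], D, ["?"] * 6)
        labels = ["a"] * 3 + ["b"] * 3
        res = permanova(dist, labels, exhaustive=True)
        assert res.r2 == pytest.approx(1.0)
        assert res.p == pytest.approx(2.0 / 20.0)
        assert res.p == pytest.approx(permanova_p_enumeration(dist.values, labels))

    def test_exhaustive_p_equals_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        dist = random_distance(6, rng)
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(dist, labels, n_perm=999, exhaustive=True)
        assert res.method == "exhaustive"
        assert res.n_perm == _n_distinct_assignments([3, 3]) == 20
        expected = permanova_p_enumeration(dist.values, labels)
        assert res.p == pytest.approx(expected, abs=1e-12)

    def test_pseudo_f_matches_direct_and_gower_routes(self):
        rng = np.random.default_rng(6)
        dist = random_distance(9, rng)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = permanova(dist, labels, n_perm=999, seed=1, exhaustive=False)
        assert res.f == pytest.approx(permanova_f_direct(dist.values, labels), rel=1e-10)
        assert res.f == pytest.approx(permanova_f_gower(dist.values, labels), rel=1e-10)

    def test_pseudo_f_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova
        rng = np.random.default_rng(7)
        dist = random_distance(10, rng)
        labels = ["a"] * 5 + ["b"] * 5
        res = permanova(dist, labels, n_perm=999, seed=2, exhaustive=False)
        dm = skbio.DistanceMatrix(dist.values, dist.pool_ids)
        sk = skbio_permanova(dm, grouping=list(labels), permutations=99)
        assert res.f == pytest.approx(float(sk["test statistic"]), rel=1e-10)

    def test_invariance_to_group_relabeling_and_pool_order(self):
        rng = np.random.default_rng(8)
        dist = random_distance(6, rng)
        labels = ["a", "b", "a", "b", "a", "b"]
        res1 = permanova(dist, labels, exhaustive=True)
        res2 = permanova(dist, ["x" if l == "a" else "y" for l in labels],
                         exhaustive=True)
        assert res1.p == res2.p and res1.f == pytest.approx(res2.f)
        perm = rng.permutation(6)
        dist_p = DistanceMatrix([dist.pool_ids[i] for i in perm],
                                dist.values[np.ix_(perm, perm)], ["?"] * 6)
        res3 = permanova(dist_p, [labels[i] for i in perm], exhaustive=True)
        assert res3.p == pytest.approx(res1.p) and res3.f == pytest.approx(res1.f)

    def test_constant_distances_report_degenerate(self):
        dist = DistanceMatrix(["a", "b", "c", "d"], np.zeros((4, 4)), ["?"] * 4)
        res = permanova(dist, ["g1", "g1", "g2", "g2"])
        assert res.p == 1.0 and "constant" in res.warning

    def test_input_validation(self):
        rng = np.random.default_rng(9)
        dist = random_distance(4, rng)
        with pytest.raises(ValueError, match="2 groups"):
            permanova(dist, ["a"] * 4)
        with pytest.raises(ValueError, match="n_perm"):
            permanova(dist, ["a", "a", "b", "b"], n_perm=10)


class TestKruskalWallis:
    def test_h_matches_rank_sum_formula(self):
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res.h == pytest.approx(3.857142857142857, abs=1e-12)
        assert res.h == pytest.approx(
            kruskal_h_direct([np.array([1., 2., 3.]), np.array([4., 5., 6.])]))
        assert res.df == 1

    def test_tie_correction_identity(self):
        vals = [1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0, 5.0]
        labels = ["a"] * 4 + ["b"] * 4
        res = kruskal_wallis(vals, labels)
        assert res.h == pytest.approx(
            kruskal_h_direct([np.asarray(vals[:4]), np.asarray(vals[4:])]),
            abs=1e-12)

    def test_all_identical_full_tie_convention(self):
        res = kruskal_wallis([2.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.h == 0.0 and res.p == 1.0 and "identical" in res.warning

    def test_permutation_p_close_to_chi2_p_at_moderate_n(self):
        rng = np.random.default_rng(10)
        vals = np.concatenate([rng.normal(0, 1, 9), rng.normal(1.5, 1, 9)])
        labels = ["a"] * 9 + ["b"] * 9
        res = kruskal_wallis(vals, labels, n_perm=2000, seed=3)
        assert res.p_perm == pytest.approx(res.p, abs=0.03)

    def test_chi2_null_p_nearly_uniform(self):
        # 4 groups of 9 from one distribution; chi-square approximation
        rng = np.random.default_rng(11)
        labels = np.repeat(["a", "b", "c", "d"], 9)
        ps = []
        for _ in range(1000):
            vals = rng.normal(size=36)
            ps.append(kruskal_wallis(vals, labels).p)
        from scipy import stats
        d, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.01


class TestMethodSummary:
    def test_within_exceeds_between_and_sd_ordering(self):
        from poolcheck import (MethodSpec, PoolDesign, align, fit_all_pairs,
                               fit_univariate, method_summary,
                               simulate_genotypes, simulate_pool_set)
        rng = np.random.default_rng(12)
        gm = simulate_genotypes(20, 900, rng=rng)
        design = PoolDesign(
            methods=(MethodSpec("CBC", 0.004, 0.98), MethodSpec("Fluor", 0.008, 0.98),
                     MethodSpec("Volume", 0.016, 0.98)),
            constructed_pools=1, extractions=3, n_animals=20, n_snps=900,
            array_noise_sd=0.003)
        pools, _ = simulate_pool_set(gm, design, rng=rng)
        data = align(gm, pools)
        fits = {pid: fit_univariate(data, pid) for pid in pools.pool_ids}
        grid = fit_all_pairs(data, univariate_fits=fits)
        methods = dict(zip(pools.pool_ids, pools.methods))
        summary = method_summary(grid, fits, methods)
        within = summary.correlation_summary.query("kind == 'within'")
        between = summary.correlation_summary.query("kind == 'between'")
        assert within["median_r"].min() > between["median_r"].max()
        sd = summary.sd_summary.set_index("method")["median_sd"]
        assert sd["Volume"] > sd["Fluor"] > sd["CBC"]

    def test_single_method_has_empty_between_table(self, medium_dataset):
        from poolcheck import fit_all_pairs, fit_univariate, method_summary
        data, _ = medium_dataset
        ids = [p for p, m in zip(data.pools.pool_ids, data.pools.methods)
               if m == "CBC"]
        fits = {pid: fit_univariate(data, pid) for pid in ids}
        grid = fit_all_pairs(data, ids, fits)
        summary = method_summary(grid, fits, {pid: "CBC" for pid in ids})
        assert (summary.correlation_summary["kind"] == "within").all()
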