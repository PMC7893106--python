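"""Univariate contribution REML: oracle equivalence, recovery, invariances."""

import numpy as np
import pandas as pd
import pytest

from poolcheck import (GenotypeMatrix, MethodSpec, PoolDataError, PoolDesign,
                       PoolFrequencyTable, align, blup_contributions,
                       filter_contaminated_pools, fit_univariate,
                       simulate_genotypes, simulate_pool_set)
from poolcheck.dense import dense_reml_loglik
from poolcheck.reml import get_workspace

from ._oracles import univariate_reml_argmax


class TestLikelihoodAgainstDense:
    @pytest.mark.parametrize("n,m,seed", [(3, 8, 0), (5, 30, 1), (4, 50, 2)])
    def test_contrast_path_equals_dense_at_random_points(self, n, m, seed):
        rng = np.random.default_rng(seed)
        gm = simulate_genotypes(n, m, rng=rng)
        design = PoolDesign(methods=(MethodSpec("CBC", 0.08, 0.9),),
                            constructed_pools=1, extractions=1,
                            n_animals=n, n_snps=m, array_noise_sd=0.02)
        pools, _ = simulate_pool_set(gm, design, rng=rng)
        data = align(gm, pools)
        ws = get_workspace(data)
        y = pools.frequencies[0]
        for _ in range(25):
            vu = 10.0 ** rng.uniform(-6, -1)
            ve = 10.0 ** rng.uniform(-6, -1)
            fast = ws.loglik(y, vu, ve)
            dense = dense_reml_loglik(ws.X, ws.Z, y, vu, ve)
            assert fast == pytest.approx(dense, abs=1e-8)

    def test_fit_matches_grid_refine_oracle_on_tiny_fixture(self, tiny_dataset):
        fit = fit_univariate(tiny_dataset, "P1")
        ws = get_workspace(tiny_dataset)
        vu_o, ve_o, ll_o = univariate_reml_argmax(
            ws.X, ws.Z, tiny_dataset.pools.frequencies_for("P1"))
        assert fit.sigma_u ** 2 == pytest.approx(vu_o, rel=1e-4)
        assert fit.sigma_e ** 2 == pytest.approx(ve_o, rel=1e-4)
        assert fit.loglik == pytest.approx(ll_o, abs=1e-6)


class TestRecovery:
    def test_zero_contribution_truth_hits_boundary(self):
        # equal weights, pure measurement noise: sigma_u consistent with zero,
        # sigma_e recovered within 10%
        su, se = [], []
        for seed in range(50):
            gm = simulate_genotypes(10, 2000, rng=seed)
            design = PoolDesign(methods=(MethodSpec("CBC", 0.0, 0.95),),
                                constructed_pools=1, extractions=1,
                                n_animals=10, n_snps=2000,
                                array_noise_sd=0.002)
            pools, _ = simulate_pool_set(gm, design, rng=seed)
            fit = fit_univariate(align(gm, pools), pools.pool_ids[0])
            su.append(fit.sigma_u)
            se.append(fit.sigma_e)
        sem = np.std(su, ddof=1) / np.sqrt(len(su))
        assert np.mean(su) <= 10.0 * max(sem, 1e-12)
        assert abs(np.mean(se) - 0.002) < 0.0002

    def test_sigma_u_recovery_midscale(self):
        ratios = []
        for seed in range(10):
            gm = simulate_genotypes(20, 1500, rng=100 + seed)
            design = PoolDesign(methods=(MethodSpec("CBC", 0.01, 0.95),),
                                constructed_pools=1, extractions=1,
                                n_animals=20, n_snps=1500,
                                array_noise_sd=0.005)
            pools, truth = simulate_pool_set(gm, design, rng=100 + seed)
            fit = fit_univariate(align(gm, pools), pools.pool_ids[0])
            ratios.append(fit.sigma_u / 0.01)
        assert abs(np.mean(ratios) - 1.0) < 0.2


class TestInvariances:
    def test_permutation_of_snps_and_animals_leaves_sigma_u(self, medium_dataset):
        data, _ = medium_dataset
        pid = data.pools.pool_ids[0]
        fit = fit_univariate(data, pid)
        rng = np.random.default_rng(0)
        snp_perm = rng.permutation(data.n_snps)
        animal_perm = rng.permutation(data.n_animals)
        gm = data.genotypes
        gm2 = GenotypeMatrix([gm.animal_ids[i] for i in animal_perm],
                             [gm.snp_ids[j] for j in snp_perm],
                             gm.dosages[np.ix_(animal_perm, snp_perm)])
        pf = data.pools
        pf2 = PoolFrequencyTable(list(pf.pool_ids),
                                 [pf.snp_ids[j] for j in snp_perm],
                                 pf.frequencies[:, snp_perm], pf.metadata)
        fit2 = fit_univariate(align(gm2, pf2), pid)
        assert fit2.sigma_u == pytest.approx(fit.sigma_u, rel=1e-6)
        assert fit2.sigma_e == pytest.approx(fit.sigma_e, rel=1e-6)

    def test_scale_equivariance(self, medium_dataset):
        data, _ = medium_dataset
        pid = data.pools.pool_ids[0]
        fit = fit_univariate(data, pid)
        c = 0.5
        pf = data.pools
        scaled = PoolFrequencyTable(list(pf.pool_ids), list(pf.snp_ids),
                                    pf.frequencies * c, pf.metadata)
        fit_c = fit_univariate(align(data.genotypes, scaled), pid)
        assert fit_c.sigma_u == pytest.approx(c * fit.sigma_u, rel=1e-6)
        assert fit_c.sigma_e == pytest.approx(c * fit.sigma_e, rel=1e-6)

    def test_blups_sum_to_zero_exactly(self, medium_dataset):
        data, _ = medium_dataset
        fit = fit_univariate(data, data.pools.pool_ids[0])
        assert fit.sigma_u > 0
        assert abs(fit.blups.sum()) < 1e-10 * max(fit.sigma_u, 1e-12) * data.n_animals

    def test_monomorphic_snps_do_not_feed_the_contribution_contrast(self):
        rng = np.random.default_rng(3)
        gm = simulate_genotypes(20, 800, rng=rng)
        design = PoolDesign(methods=(MethodSpec("CBC", 0.02, 0.95),),
                            constructed_pools=1, extractions=1,
                            n_animals=20, n_snps=800, array_noise_sd=0.004)
        pools, truth = simulate_pool_set(gm, design, rng=rng)
        data = align(gm, pools)
        fit = fit_univariate(data, pools.pool_ids[0])
        ws = get_workspace(data)

        n_mono = 200
        mono = np.tile(rng.choice([0.0, 1.0, 2.0], n_mono), (20, 1))
        y_mono = truth.weights[0] @ (mono / 2.0) + rng.normal(0, 0.004, n_mono)
        gm2 = GenotypeMatrix(gm.animal_ids, gm.snp_ids + [f"M{j}" for j in range(n_mono)],
                             np.hstack([gm.dosages, mono]))
        pf2 = PoolFrequencyTable(
            pools.pool_ids, gm2.snp_ids,
            np.clip(np.hstack([pools.frequencies, np.tile(y_mono, (1, 1))]), 0, 1),
            pools.metadata)
        data2 = align(gm2, pf2)
        ws2 = get_workspace(data2)
        fit2 = fit_univariate(data2, pools.pool_ids[0])
        # the random-effect contrast is unchanged in rank; sigma_u barely moves
        assert ws2.rank == ws.rank
        assert fit2.sigma_u == pytest.approx(fit.sigma_u, rel=0.02)


class TestFlagging:
    def test_null_blups_when_frequencies_equal_expectation(self):
        gm = simulate_genotypes(8, 60, rng=4)
        design = PoolDesign(methods=(MethodSpec("CBC", 0.0, 0.95),),
                            constructed_pools=1, extractions=1,
                            n_animals=8, n_snps=60, array_noise_sd=0.0)
        pools, _ = simulate_pool_set(gm, design, rng=4)
        data = align(gm, pools)
        fit = fit_univariate(data, pools.pool_ids[0])
        rep = blup_contributions(fit, data)
        np.testing.assert_allclose(rep.blups, 0.0, atol=1e-10)
        assert not rep.flags.any()
        assert "boundary" in rep.note or fit.boundary

    def test_single_contaminated_animal_flagged(self):
        from poolcheck.simulate import ContaminationSpec
        gm = simulate_genotypes(50, 3000, rng=0)
        design = PoolDesign(methods=(MethodSpec("Fluor", 0.006, 0.95),),
                            constructed_pools=1, extractions=1,
                            n_animals=50, n_snps=3000)
        spec = ContaminationSpec("Fluor 1-1", (gm.animal_ids[10],), 3.0)
        pools, _ = simulate_pool_set(gm, design, [spec], rng=0)
        data = align(gm, pools)
        rep = blup_contributions(fit_univariate(data, "Fluor 1-1"), data)
        assert rep.flagged_animals == [gm.animal_ids[10]]

    def test_filter_contract(self):
        import types
        mk = lambda pid, flagged: types.SimpleNamespace(
            pool_id=pid, flagged_animals=flagged, threshold=3.0)
        reports = {"a": mk("a", []), "b": mk("b", ["A1"]), "c": mk("c", [])}
        res = filter_contaminated_pools(reports)
        assert res.retained == ["a", "c"]
        assert "A1" in res.excluded["b"]
        clean = filter_contaminated_pools({"a": mk("a", [])})
        assert clean.retained == ["a"] and not clean.excluded
        with pytest.warns(UserWarning, match="all pools excluded"):
            res = filter_contaminated_pools({"b": mk("b", ["A1"])})
        assert res.retained == []


class TestErrorContracts:
    def test_too_few_snps_errors(self):
        gm = simulate_genotypes(10, 8, rng=1)
        with pytest.warns(UserWarning, match="under-identified"):
            design = PoolDesign(methods=(MethodSpec("CBC", 0.01, 0.95),),
                                constructed_pools=1, extractions=1,
                                n_animals=10, n_snps=8)
        pools, _ = simulate_pool_set(gm, design, rng=1)
        data = align(gm, pools)
        with pytest.raises(PoolDataError, match="fewer than"):
            fit_univariate(data, pools.pool_ids[0])

    def test_unknown_pool_errors(self, tiny_dataset):
        with pytest.raises(PoolDataError, match="unknown pool"):
            fit_univariate(tiny_dataset, "nope")
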