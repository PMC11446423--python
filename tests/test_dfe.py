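"""DFE fits, the dominance scan, AIC machinery and model averaging."""

import numpy as np
import pytest

from dominfer.dfe import (
    BIN_EDGES,
    DiscreteDFE,
    DominanceMap,
    FitResult,
    GammaDFE,
    akaike_model_average,
    bin_mean_s,
    compute_aic,
    enumerate_and_scan,
    enumerate_dominance_maps,
    expected_sfs_discrete,
    expected_sfs_gamma,
    fit_discrete_dfe,
    fit_gamma_dfe,
    select_models,
    summarize_hs,
)
from dominfer.models import simulation_model
from dominfer.spectra import SFSpectrum
from dominfer.synth import DESK_DEMOGRAPHY, sample_poisson_sfs

from .conftest import DESK_N, DESK_N_ANC, DESK_THETA_S

THETA_NS = 2.31 * DESK_THETA_S


class TestAIC:
    def test_values_from_reported_likelihoods(self):
        assert np.isclose(compute_aic(-1450.58, 2), 2905.16)
        assert np.isclose(compute_aic(-1452.97, 4), 2913.94)
        assert np.isclose(compute_aic(-1452.97, 4) - compute_aic(-1450.58, 2), 8.78)

    def test_degenerate(self):
        assert compute_aic(0.0, 0) == 0.0
        with pytest.raises(ValueError):
            compute_aic(0.0, -1)

    def test_identity_on_fit_results(self):
        r = FitResult(
            model=DiscreteDFE(np.full(5, 0.2)),
            dominance=DominanceMap.uniform(0.5),
            LL=-123.4, k=4, n_starts=1,
        )
        assert r.AIC == 2 * 4 - 2 * (-123.4)


class TestSelection:
    def _results(self, lls, hs=None):
        out = []
        for j, ll in enumerate(lls):
            h = hs[j] if hs else (0.5, 0.5, 0.5, 0.5, 0.5)
            out.append(
                FitResult(model=DiscreteDFE(np.full(5, 0.2)),
                          dominance=DominanceMap(h), LL=ll, k=4, n_starts=1)
            )
        return out

    def test_cutoff_threshold(self):
        kept = select_models(self._results([-1451.68, -1455.0, -1457.0]))
        assert len(kept) == 2

    def test_monotone_definitions(self):
        assert DominanceMap((0.5, 0.45, 0.45, 0.15, 0.05)).monotone
        assert not DominanceMap((0.5, 0.25, 0.35, 0.15, 0.05)).monotone

    def test_monotonic_filter(self):
        res = self._results(
            [-10.0, -10.5],
            hs=[(0.5, 0.45, 0.45, 0.15, 0.05), (0.5, 0.25, 0.35, 0.15, 0.05)],
        )
        assert len(select_models(res, monotonic_only=True)) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_models([])


class TestModelAverage:
    def test_equal_aic_is_simple_mean(self):
        a = FitResult(model=DiscreteDFE([1, 0, 0, 0, 0]),
                      dominance=DominanceMap.uniform(0.1), LL=-5.0, k=4, n_starts=1)
        b = FitResult(model=DiscreteDFE([0, 1, 0, 0, 0]),
                      dominance=DominanceMap.uniform(0.3), LL=-5.0, k=4, n_starts=1)
        avg = akaike_model_average([a, b])
        np.testing.assert_allclose(avg.weights, [0.5, 0.5])
        np.testing.assert_allclose(avg.averaged_proportions, [0.5, 0.5, 0, 0, 0])
        np.testing.assert_allclose(avg.averaged_h, [0.2] * 5)

    def test_delta_aic_two_weights(self):
        a = FitResult(model=DiscreteDFE([1, 0, 0, 0, 0]),
                      dominance=DominanceMap.uniform(0.5), LL=0.0, k=4, n_starts=1)
        b = FitResult(model=DiscreteDFE([0, 1, 0, 0, 0]),
                      dominance=DominanceMap.uniform(0.5), LL=-1.0, k=4, n_starts=1)
        w = akaike_model_average([a, b]).weights
        expect = np.array([1.0, np.exp(-1.0)])
        np.testing.assert_allclose(w, expect / expect.sum())
        assert np.isclose(w.sum(), 1.0, atol=1e-12)

    def test_single_model_returned_exactly(self):
        p = np.array([0.3, 0.1, 0.2, 0.25, 0.15])
        a = FitResult(model=DiscreteDFE(p), dominance=DominanceMap.uniform(0.25),
                      LL=-9.0, k=4, n_starts=1)
        avg = akaike_model_average([a])
        np.testing.assert_array_equal(avg.averaged_proportions, p)
        assert avg.average_h_overall == a.mean_h

    def test_convex_hull_property(self):
        rng = np.random.default_rng(5)
        results = []
        for _ in range(6):
            p = rng.dirichlet(np.ones(5))
            h = tuple(rng.uniform(0, 0.5, 5))
            results.append(FitResult(model=DiscreteDFE(p), dominance=DominanceMap(h),
                                     LL=rng.uniform(-20, -10), k=4, n_starts=1))
        avg = akaike_model_average(results)
        ps = np.array([r.proportions for r in results])
        assert np.all(avg.averaged_proportions <= ps.max(0) + 1e-12)
        assert np.all(avg.averaged_proportions >= ps.min(0) - 1e-12)


class TestSummaries:
    def test_preset_weighted_mean_h(self):
        dfe, dmap = simulation_model("strongly_recessive")
        r = FitResult(model=dfe, dominance=dmap, LL=0.0, k=4, n_starts=1)
        s = summarize_hs(r)
        assert abs(s["mean_h"] - 0.26) < 0.005

    def test_zero_h_bins_contribute_nothing(self):
        r = FitResult(model=DiscreteDFE(np.full(5, 0.2)),
                      dominance=DominanceMap((0.0,) * 5), LL=0.0, k=4, n_starts=1)
        s = summarize_hs(r)
        assert s["mean_hs_space"] == 0.0 and s["mean_hs_inferred"] == 0.0

    def test_bin_means_are_arithmetic_midpoints(self):
        np.testing.assert_allclose(
            bin_mean_s(), [(a + b) / 2 for a, b in zip(BIN_EDGES[:-1], BIN_EDGES[1:])]
        )


class TestExpectedSFS:
    def test_single_bin_limit_is_neutral(self, desk_grids):
        dfe = DiscreteDFE([1, 0, 0, 0, 0])
        exp = expected_sfs_discrete(dfe, DominanceMap.uniform(0.5), desk_grids, 100.0)
        np.testing.assert_allclose(exp.counts, 100.0 * desk_grids[0.5].neutral_row)

    def test_mixture_linearity(self, desk_grids):
        dmap = DominanceMap.uniform(0.5)
        p1 = DiscreteDFE([0.4, 0.2, 0.1, 0.2, 0.1])
        p2 = DiscreteDFE([0.1, 0.1, 0.3, 0.3, 0.2])
        mix = DiscreteDFE(0.5 * p1.proportions + 0.5 * p2.proportions)
        a = expected_sfs_discrete(p1, dmap, desk_grids, THETA_NS).counts
        b = expected_sfs_discrete(p2, dmap, desk_grids, THETA_NS).counts
        c = expected_sfs_discrete(mix, dmap, desk_grids, THETA_NS).counts
        np.testing.assert_allclose(c, 0.5 * a + 0.5 * b, rtol=1e-12)

    def test_gamma_beta_to_zero_is_neutral(self, desk_grids):
        dfe = GammaDFE(0.5, 1e-9)
        exp = expected_sfs_gamma(dfe, 0.5, desk_grids[0.5], THETA_NS)
        np.testing.assert_allclose(
            exp.counts, THETA_NS * desk_grids[0.5].neutral_row, rtol=1e-6
        )

    def test_gamma_delta_limit_matches_grid_row(self, desk_grids):
        """Large shape with fixed mean concentrates on one grid row."""
        grid = desk_grids[0.5]
        s0 = grid.s_values[70]
        dfe = GammaDFE(3000.0, s0 / 3000.0)
        exp = expected_sfs_gamma(dfe, 0.5, grid, 1.0)
        direct = grid.expected[71]
        mass = direct / direct.sum()
        keep = mass > 1e-6
        assert np.max(np.abs(exp.counts[keep] / direct[keep] - 1.0)) < 0.05

    def test_total_decreases_with_scale(self, desk_grids):
        grid = desk_grids[0.5]
        totals = [
            expected_sfs_gamma(GammaDFE(0.2, b), 0.5, grid, 1.0).counts.sum()
            for b in (1e-4, 1e-3, 1e-2, 1e-1)
        ]
        assert np.all(np.diff(totals) < 0)

    def test_missing_grid_reported(self, desk_grids):
        dmap = DominanceMap((0.5, 0.45, 0.3, 0.15, 0.05))  # 0.3 not built
        with pytest.raises(KeyError, match="0.3"):
            expected_sfs_discrete(DiscreteDFE(np.full(5, 0.2)), dmap, desk_grids, 1.0)


class TestFits:
    def test_gamma_self_consistency(self, desk_grids):
        grid = desk_grids[0.5]
        truth = GammaDFE(0.2, 0.05)
        mean = expected_sfs_gamma(truth, 0.5, grid, THETA_NS)
        noiseless = SFSpectrum(mean.counts, n=DESK_N, folded=True)
        fit = fit_gamma_dfe(noiseless, 0.5, grid, THETA_NS, n_starts=3, seed=0)
        assert abs(fit.model.alpha / 0.2 - 1) < 1e-3
        assert abs(fit.model.beta / 0.05 - 1) < 1e-2

    def test_gamma_recovery_across_seeds(self, desk_grids):
        """Shape recovered within 15% per seed; mean E[s] unbiased within 10%."""
        grid = desk_grids[0.5]
        truth = GammaDFE(0.2, 0.05)
        mean = expected_sfs_gamma(truth, 0.5, grid, THETA_NS)
        es_rel = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            obs = SFSpectrum(rng.poisson(mean.counts).astype(float),
                             n=DESK_N, folded=True)
            fit = fit_gamma_dfe(obs, 0.5, grid, THETA_NS, n_starts=5, seed=seed)
            assert abs(fit.model.alpha / truth.alpha - 1) < 0.15
            es_rel.append(fit.model.E_s / truth.E_s - 1)
        assert abs(np.mean(es_rel)) < 0.10

    def test_discrete_noiseless_recovery(self, desk_grids):
        dfe, dmap = simulation_model("strongly_recessive")
        mean = expected_sfs_discrete(dfe, dmap, desk_grids, THETA_NS)
        noiseless = SFSpectrum(mean.counts, n=DESK_N, folded=True)
        fit = fit_discrete_dfe(noiseless, dmap, desk_grids, THETA_NS, n_starts=1)
        assert np.max(np.abs(fit.model.proportions - dfe.proportions)) < 1e-4

    def test_discrete_recovery_across_seeds(self, desk_grids):
        """Identifiable recovery: the neutral and nearly-neutral bins are
        pooled (their split is a likelihood ridge); pooled errors stay below
        0.1 per seed and the estimates are unbiased within 0.05."""
        dfe, dmap = simulation_model("strongly_recessive")
        errors = []
        for seed in range(10):
            ds = sample_poisson_sfs(
                DESK_DEMOGRAPHY, dfe, dmap, DESK_THETA_S, DESK_N, desk_grids, seed
            )
            fit = fit_discrete_dfe(ds.nonsyn_sfs, dmap, desk_grids, THETA_NS,
                                   n_starts=1, seed=seed)
            p, pt = fit.model.proportions, dfe.proportions
            err = np.array([p[0] + p[1] - pt[0] - pt[1],
                            p[2] - pt[2], p[3] - pt[3], p[4] - pt[4]])
            assert np.max(np.abs(err)) < 0.10
            assert abs(err[3]) < 0.05  # strongly deleterious bin
            errors.append(err)
        assert np.max(np.abs(np.mean(errors, axis=0))) < 0.05

    def test_likelihood_concave_along_simplex_edges(self, desk_grids):
        from dominfer.spectra import poisson_loglik

        dfe, dmap = simulation_model("strongly_recessive")
        ds = sample_poisson_sfs(
            DESK_DEMOGRAPHY, dfe, dmap, DESK_THETA_S, DESK_N, desk_grids, seed=3
        )
        fit = fit_discrete_dfe(ds.nonsyn_sfs, dmap, desk_grids, THETA_NS, n_starts=1)
        p0 = fit.model.proportions

        def ll_at(p):
            exp = expected_sfs_discrete(DiscreteDFE(p / p.sum()), dmap,
                                        desk_grids, THETA_NS)
            return poisson_loglik(ds.nonsyn_sfs, exp)

        eps = 1e-3
        for a in range(5):
            for b in range(a + 1, 5):
                d = np.zeros(5)
                d[a], d[b] = eps, -eps
                if np.any(p0 + d < 0) or np.any(p0 - d < 0):
                    continue
                second = ll_at(p0 + d) - 2 * ll_at(p0) + ll_at(p0 - d)
                assert second <= 1e-6


class TestScan:
    def test_enumeration_size(self):
        assert sum(1 for _ in enumerate_dominance_maps()) == 4096 == 8**4

    def test_neutral_bin_pinned(self):
        for dmap in enumerate_dominance_maps(h_set=(0.0, 0.5)):
            assert dmap.h_per_bin[0] == 0.5

    def test_degenerate_scan_equals_single_fit(self, desk_grids):
        dfe, dmap_t = simulation_model("strongly_recessive")
        ds = sample_poisson_sfs(
            DESK_DEMOGRAPHY, dfe, dmap_t, DESK_THETA_S, DESK_N, desk_grids, seed=9
        )
        res = enumerate_and_scan(ds.nonsyn_sfs, desk_grids, THETA_NS,
                                 h_set=(0.5,), seed=0)
        assert len(res) == 1
        single = fit_discrete_dfe(ds.nonsyn_sfs, DominanceMap.uniform(0.5),
                                  desk_grids, THETA_NS, n_starts=1, seed=0)
        assert np.isclose(res[0].LL, single.LL, atol=1e-6)

    def test_scan_deterministic(self, desk_grids):
        dfe, dmap_t = simulation_model("strongly_recessive")
        ds = sample_poisson_sfs(
            DESK_DEMOGRAPHY, dfe, dmap_t, DESK_THETA_S, DESK_N, desk_grids, seed=4
        )
        lls = []
        for _ in range(2):
            res = enumerate_and_scan(ds.nonsyn_sfs, desk_grids, THETA_NS,
                                     h_set=(0.05, 0.45), seed=11)
            lls.append(np.array([r.LL for r in res]))
        assert len(lls[0]) == 2**4
        np.testing.assert_array_equal(lls[0], lls[1])
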