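"""Diffusion expectations against closed forms and the discrete-WF oracle.

The matrix-oracle comparisons are restricted to entries carrying at least
1e-4 of the spectrum's mass: below that the discrete Wright-Fisher model and
the diffusion genuinely part ways in the large-deviation tail, at any grid
resolution, so those entries say nothing about the numerics under test.
"""

import numpy as np
import pytest

from dominfer.demomodel import DemographicModel, Epoch, three_epoch_model
from dominfer.diffusion import (
    build_expectation_grid,
    demographic_expected_sfs,
    equilibrium_density,
    equilibrium_expected_sfs,
    evolve_density,
    expected_sfs_from_density,
    frequency_grid,
    quasi_stationary_density,
    ScaledSelection,
)
from dominfer.spectra import fold_sfs

from .oracles import quasi_stationary_reference, wf_matrix_sfs

MASS_FLOOR = 1e-4


def _masked_max_rel(mine, oracle):
    keep = oracle / oracle.sum() > MASS_FLOOR
    return np.max(np.abs(mine[keep] / oracle[keep] - 1.0))


class TestQuasiStationaryDensity:
    def test_neutral_is_inverse_frequency(self):
        q = np.linspace(0.01, 0.99, 50)
        np.testing.assert_allclose(
            quasi_stationary_density(0.0, 0.3, q), 1.0 / q, rtol=1e-12
        )

    def test_matches_adaptive_quadrature(self):
        """Random (q, gamma, h) against scipy adaptive quadrature, 1e-6 relative."""
        rng = np.random.default_rng(99)
        for _ in range(25):
            q = rng.uniform(0.02, 0.95)
            gamma = rng.uniform(-80.0, 20.0)
            h = rng.uniform(0.0, 1.0)
            ref = quasi_stationary_reference(q, gamma, h)
            mine = quasi_stationary_density(gamma, h, np.array([q]))[0]
            assert abs(mine / ref - 1.0) < 1e-6, (q, gamma, h)

    def test_additive_reduces_to_genic_closed_form(self):
        """At h = 1/2 the q^2 term vanishes and f has the classic genic form."""
        q = np.linspace(0.05, 0.9, 20)
        for gamma in (-12.0, 4.0):
            expected = (1.0 - np.exp(-2 * gamma * (1 - q))) / (
                q * (1 - q) * (1.0 - np.exp(-2 * gamma))
            )
            np.testing.assert_allclose(
                quasi_stationary_density(gamma, 0.5, q), expected, rtol=1e-8
            )

    def test_rejects_boundary_points(self):
        with pytest.raises(ValueError):
            quasi_stationary_density(1.0, 0.5, np.array([0.0, 0.5]))


class TestEquilibriumSFS:
    def test_neutral_closed_form(self):
        """Constant size, theta=1: E[x_i] = 1/i within 1e-4 relative."""
        n = 20
        sfs = equilibrium_expected_sfs(0.0, 0.5, n, theta=1.0, pts=1000)
        i = np.arange(1, n)
        assert np.max(np.abs(sfs.counts * i - 1.0)) < 1e-4

    def test_n2_entry_is_expected_heterozygosity(self):
        phi = equilibrium_density(-8.0, 0.3, pts=1500)
        sfs = expected_sfs_from_density(phi, 2, theta=1.0)
        xi, fi = phi.q_grid[1:-1], phi.phi[1:-1]
        direct = np.trapezoid(2 * xi * (1 - xi) * fi, xi)
        assert np.isclose(sfs.counts[0], direct, rtol=1e-3)

    @pytest.mark.parametrize(
        "gamma,h",
        [(2, 0.0), (2, 0.25), (2, 0.5), (2, 1.0),
         (5, 0.0), (5, 0.25), (5, 0.5),
         (10, 0.0), (10, 0.25)],
    )
    def test_matches_wf_matrix_oracle(self, gamma, h):
        """Folded equilibrium SFS vs the binomial transition matrix, 5%."""
        N, n = 400, 16
        oracle = wf_matrix_sfs(N, gamma / (2 * N), h, n)
        mine = fold_sfs(equilibrium_expected_sfs(-gamma, h, n, pts=2000)).counts
        assert _masked_max_rel(mine, oracle) < 0.05

    def test_coarse_grid_warns(self):
        from dominfer.diffusion import FrequencyDensity

        xx = np.linspace(0.0, 1.0, 51)  # uniform: no boundary crowding
        phi = FrequencyDensity(xx, np.concatenate(([0.0], 1.0 / xx[1:-1], [0.0])))
        with pytest.warns(RuntimeWarning, match="too coarse"):
            expected_sfs_from_density(phi, 400, theta=1.0)


class TestEvolveDensity:
    def test_neutral_constant_epoch_is_stationary(self):
        start = equilibrium_density(0.0, 0.5, 300)
        out = evolve_density(start, DemographicModel((Epoch(1, 1, 0.5),)), 0.0, 0.5)
        xi = out.q_grid[1:-1]
        # interior profile stays 1/q; the outermost cells feel the absorbers
        inner = (xi > 1e-3) & (xi < 0.995)
        assert np.max(np.abs(out.phi[1:-1][inner] * xi[inner] - 1.0)) < 0.01

    def test_expansion_approaches_scaled_equilibrium(self):
        """After a long 2x expansion the expected SFS approaches 2/i."""
        n, i = 20, np.arange(1, 20)
        sfs = demographic_expected_sfs(
            0.0, 0.5, DemographicModel((Epoch(2, 2, 20.0),)), n, pts=(150, 225, 300)
        )
        assert np.max(np.abs(sfs.counts * i / 2.0 - 1.0)) < 0.02

    @pytest.mark.parametrize(
        "gamma,h",
        [(0, 0.5), (0, 0.0), (5, 0.0), (5, 0.5), (5, 1.0), (10, 0.2), (10, 0.5)],
    )
    def test_bottleneck_matches_wf_matrix_oracle(self, gamma, h):
        """Bottleneck + recovery transient vs the time-stepped matrix, 5%."""
        N_anc, n = 250, 16
        dem = DemographicModel((Epoch(0.35, 0.35, 0.08), Epoch(1.4, 1.4, 0.05)))
        oracle = wf_matrix_sfs(
            N_anc, gamma / (2 * N_anc), h, n, epochs=[(87, 40), (350, 25)]
        )
        mine = fold_sfs(
            demographic_expected_sfs(-gamma, h, dem, n, pts=(300, 450, 600))
        ).counts
        assert _masked_max_rel(mine, oracle) < 0.05

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            Epoch(-1.0, -1.0, 0.1)

    def test_grid_refinement_converged(self):
        """Doubling the (extrapolated) default grid moves mass-bearing
        entries by < 0.1%."""
        dem = three_epoch_model(0.2, 0.05, 0.7, 0.06, 4.0, 0.03)
        for gamma in (-10.0, -100.0):
            a = demographic_expected_sfs(gamma, 0.3, dem, 20, pts=(300, 450, 600))
            b = demographic_expected_sfs(gamma, 0.3, dem, 20, pts=(600, 900, 1200))
            mass = b.counts / b.counts.sum()
            keep = mass > 1e-6
            assert np.max(np.abs(a.counts[keep] / b.counts[keep] - 1.0)) < 1e-3


@pytest.fixture(scope="module")
def small_grid(tmp_path_factory):
    dem = three_epoch_model(0.2, 0.05, 0.7, 0.06, 4.0, 0.03)
    cache = tmp_path_factory.mktemp("grid_cache")
    grid = build_expectation_grid(
        0.3, dem, 16, 1000.0, n_points=40, pts=250, cache_dir=cache
    )
    return grid, dem, cache


class TestExpectationGrid:

    def test_rows_nonnegative_and_continuous(self, small_grid):
        grid, _, _ = small_grid
        assert np.all(grid.expected >= 0)
        # regression guard: total expected segregating sites varies smoothly
        # between adjacent gamma rows (tail entries decay super-exponentially
        # in gamma, so the guard is on the mass-carrying aggregate)
        tot = grid.expected[1:].sum(axis=1)
        assert np.max(np.abs(np.diff(np.log(tot)))) < 0.5

    def test_neutral_row_matches_neutral_build(self, small_grid):
        grid, dem, _ = small_grid
        direct = fold_sfs(demographic_expected_sfs(0.0, 0.3, dem, 16, pts=250))
        np.testing.assert_array_equal(grid.neutral_row, direct.counts)

    def test_singletons_decrease_with_selection_strength(self, small_grid):
        grid, _, _ = small_grid
        singletons = grid.expected[1:, 0]
        strong = grid.gamma_values > 5.0  # beyond the drift-dominated regime
        d = np.diff(singletons[strong])
        assert np.all(d <= 1e-9)

    def test_cache_reload_bit_identical(self, small_grid):
        grid, dem, cache = small_grid
        again = build_expectation_grid(
            0.3, dem, 16, 1000.0, n_points=40, pts=250, cache_dir=cache
        )
        np.testing.assert_array_equal(grid.expected, again.expected)

    def test_neutral_row_equal_across_h(self, tmp_path):
        dem = three_epoch_model(0.2, 0.05, 0.7, 0.06, 4.0, 0.03)
        g1 = build_expectation_grid(0.1, dem, 16, 1000.0, n_points=5, pts=200)
        g2 = build_expectation_grid(0.9, dem, 16, 1000.0, n_points=5, pts=200)
        np.testing.assert_array_equal(g1.neutral_row, g2.neutral_row)

    def test_s_beyond_supported_range_rejected(self):
        dem = three_epoch_model(0.2, 0.05, 0.7, 0.06, 4.0, 0.03)
        with pytest.raises(ValueError, match="truncate"):
            build_expectation_grid(0.5, dem, 16, 1000.0, s_range=(1e-5, 0.4))


class TestScaledSelection:
    def test_gamma_consistency(self):
        sel = ScaledSelection.from_s(0.01, 0.2, N_anc=5000)
        assert sel.gamma == 100.0
        assert sel.signed_gamma == -100.0

    def test_bounds(self):
        with pytest.raises(ValueError):
            ScaledSelection.from_s(0.6, 0.5, 1000)
        with pytest.raises(ValueError):
            ScaledSelection.from_s(0.1, 1.5, 1000)


def test_frequency_grid_shape():
    g = frequency_grid(101)
    assert g[0] == 0.0 and g[-1] == 1.0
    assert np.all(np.diff(g) > 0)
    # crowding: boundary steps much finer than central steps
    assert g[1] < 1e-3 and np.max(np.diff(g)) > 5 * g[1]
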