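"""Autocorrelation and free-energy landscape construction."""

import numpy as np
import pytest

from hairpinlab.fel import (
    KB_KJ_PER_MOL_K,
    autocorrelation,
    basin_extract,
    free_energy_map,
    local_minima,
    overlay_trajectory,
)


class TestAutocorrelation:
    def test_constant_series_raw_value(self):
        result = autocorrelation(np.full(10, 2.0), max_lag=5, variant="raw")
        np.testing.assert_allclose(result.values, 4.0)

    def test_alternating_series_hand_computed(self):
        # f = (1, -1, 1, -1): lag 0 -> 1, lag 1 -> -1, lag 2 -> 1
        result = autocorrelation(np.array([1.0, -1.0, 1.0, -1.0]),
                                 max_lag=2, variant="raw")
        np.testing.assert_allclose(result.values, [1.0, -1.0, 1.0])

    def test_raw_lag0_is_mean_square(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=200)
        result = autocorrelation(f, max_lag=0, variant="raw")
        assert result.values[0] == pytest.approx(np.mean(f * f))

    def test_normalized_starts_at_one(self):
        rng = np.random.default_rng(1)
        result = autocorrelation(rng.normal(size=50), max_lag=10)
        assert result.values[0] == pytest.approx(1.0)

    def test_ar1_matches_closed_form(self):
        """Normalized ACF of an AR(1) process equals rho^lag (Bartlett SE)."""
        rho, n = 0.9, 100_000
        rng = np.random.default_rng(12345)
        noise = rng.normal(size=n)
        f = np.empty(n)
        f[0] = noise[0] / np.sqrt(1 - rho * rho)
        for t in range(1, n):
            f[t] = rho * f[t - 1] + noise[t]
        result = autocorrelation(f, max_lag=20)
        for k in range(1, 21):
            se = np.sqrt(
                ((1 - rho ** (2 * k)) * (1 + rho * rho) / (1 - rho * rho)
                 - 2 * k * rho ** (2 * k)) / n
            )
            assert abs(result.values[k] - rho ** k) < 3 * se, f"lag {k}"

    def test_lag_axis_in_time_units(self):
        result = autocorrelation(np.arange(6.0), max_lag=3, frame_interval=2.0)
        np.testing.assert_allclose(result.lags, [0.0, 2.0, 4.0, 6.0])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            autocorrelation(np.array([1.0]))
        with pytest.raises(ValueError):
            autocorrelation(np.arange(5.0), max_lag=5)
        with pytest.raises(ValueError):
            autocorrelation(np.arange(5.0), variant="whatever")


class TestFreeEnergyMap:
    def test_uniform_occupancy_is_zero_everywhere(self):
        edges = (np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
        x = np.array([0.5, 0.5, 1.5, 1.5])
        y = np.array([0.5, 1.5, 0.5, 1.5])
        fel = free_energy_map(x, y, bins=edges, temperature=300.0)
        np.testing.assert_allclose(fel.delta_g.compressed(), 0.0)

    def test_two_bin_ratio_closed_form(self):
        edges = (np.array([0.0, 1.0, 2.0]), np.array([0.0, 2.0, 4.0]))
        x = np.concatenate([np.full(100, 0.5), np.full(50, 1.5)])
        y = np.full(150, 1.0)
        fel = free_energy_map(x, y, bins=edges, temperature=300.0)
        expected = KB_KJ_PER_MOL_K * 300.0 * np.log(2.0)
        assert fel.delta_g[0, 0] == 0.0
        assert fel.delta_g[1, 0] == pytest.approx(expected)

    def test_global_minimum_bin_is_zero(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=500), rng.normal(size=500)
        fel = free_energy_map(x, y, temperature=310.0, bin_width=0.5)
        assert fel.delta_g[fel.minimum_bin] == 0.0
        assert float(fel.delta_g.min()) == 0.0

    def test_counts_conserved_and_mask_matches_empties(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=300), rng.normal(size=300)
        fel = free_energy_map(x, y, bin_width=0.25)
        assert fel.n_samples == 300
        np.testing.assert_array_equal(fel.delta_g.mask, fel.counts == 0)

    def test_adding_uniform_counts_contracts_spread(self):
        """Boltzmann inversion: a constant added to every bin shrinks dG."""
        edges = (np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
        x = np.concatenate([np.full(64, 0.5), np.full(4, 1.5)])
        y = np.full(68, 0.5)
        base = free_energy_map(x, y, bins=edges)
        boosted_x = np.concatenate([x, np.full(20, 0.5), np.full(20, 1.5)])
        boosted_y = np.full(boosted_x.size, 0.5)
        boosted = free_energy_map(boosted_x, boosted_y, bins=edges)
        assert boosted.delta_g.max() < base.delta_g.max()

    def test_sample_order_irrelevant(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=200), rng.normal(size=200)
        perm = rng.permutation(200)
        a = free_energy_map(x, y, bin_width=0.5)
        b = free_energy_map(x[perm], y[perm], bin_width=0.5)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            free_energy_map(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            free_energy_map(np.ones(3), np.ones(3), temperature=0.0)


def _two_well_map(seed=0, n=4000, separation=2.0):
    rng = np.random.default_rng(seed)
    n2 = n // 4
    x = np.concatenate([rng.normal(0, 0.25, n - n2),
                        rng.normal(separation, 0.25, n2)])
    y = np.concatenate([rng.normal(0, 0.25, n - n2),
                        rng.normal(0, 0.25, n2)])
    return free_energy_map(x, y, temperature=300.0, bin_width=0.25)


class TestBasins:
    def test_single_occupied_bin(self):
        edges = (np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
        fel = free_energy_map(np.full(5, 0.5), np.full(5, 0.5), bins=edges)
        basin = basin_extract(fel, threshold=1.0)
        assert basin.member_bins == {(0, 0)}
        assert basin.rmsd_range == (0.0, 1.0) and basin.rg_range == (0.0, 1.0)

    def test_ridge_separates_wells(self):
        fel = _two_well_map()
        basin = basin_extract(fel, threshold=1.5)
        # the minor well is ~kT ln 3 ~ 2.7 kJ/mol above the major one and
        # separated by an empty/high ridge: it must not join the basin
        centers = 0.5 * (fel.x_edges[:-1] + fel.x_edges[1:])
        members_x = [centers[i] for i, _ in basin.member_bins]
        assert max(members_x) < 1.0

    def test_infinite_threshold_collects_connected_bins(self):
        edges = (np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 2.0]))
        x = np.array([0.5, 0.5, 1.5])
        y = np.array([0.5, 1.5, 1.5])
        fel = free_energy_map(x, y, bins=edges)
        basin = basin_extract(fel, threshold=np.inf)
        assert basin.member_bins == {(0, 0), (0, 1), (1, 1)}

    def test_two_wells_found_as_local_minima(self):
        fel = _two_well_map()
        basins = local_minima(fel, threshold=4.0)
        assert len(basins) >= 2
        assert basins[0].min_delta_g == 0.0
        assert basins[0].min_delta_g <= basins[1].min_delta_g

    def test_negative_threshold_yields_nothing(self):
        fel = _two_well_map()
        assert local_minima(fel, threshold=-1.0) == []
        with pytest.raises(ValueError):
            basin_extract(fel, threshold=-1.0)


class TestOverlay:
    def test_source_samples_visit_only_defined_bins(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=300), rng.normal(size=300)
        fel = free_energy_map(x, y, bin_width=0.5)
        visited, frac, n_out = overlay_trajectory(fel, x, y)
        assert n_out == 0 and frac == 1.0
        assert not np.any(visited & fel.delta_g.mask)

    def test_all_samples_outside(self):
        fel = _two_well_map()
        x = np.full(10, 100.0)
        visited, frac, n_out = overlay_trajectory(fel, x, x)
        assert n_out == 10 and frac == 0.0 and not visited.any()

    def test_basin_occupancy_fraction(self):
        fel = _two_well_map()
        basin = basin_extract(fel, threshold=2.5)
        rng = np.random.default_rng(6)
        x = rng.normal(0, 0.1, 200)
        y = rng.normal(0, 0.1, 200)
        _, frac, _ = overlay_trajectory(fel, x, y, basin=basin)
        assert frac > 0.5
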