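import numpy as np
import pytest

from crossmap.shuffles import (
    ShuffleEnsemble,
    SignificanceResult,
    classify_distance_cell,
    corrected_alpha,
    odd_even_stability,
    rigid_shuffle,
    rigid_shuffle_times,
    significant_bins,
    solo_pools,
    solo_projection_shuffle,
    spikes_to_distance,
    switch_times,
)
from crossmap.synth import simulate_spikes
from crossmap.synth.model import DistanceProfile
from crossmap.tuning import distance_tuning

from conftest import make_profiled_cell


def test_corrected_alpha_is_half_percent():
    # (5% / 40 bins) * 4-bin width = 0.5% two-sided
    assert corrected_alpha() == pytest.approx(0.005)


class TestRigidShuffle:
    def test_per_flight_counts_conserved(self, rng):
        spikes = np.sort(rng.uniform(0, 100, 200))
        windows = [(0.0, 30.0), (40.0, 70.0), (80.0, 100.0)]
        out = rigid_shuffle_times(spikes, windows, 50, rng)
        for (t0, t1) in windows:
            n_data = ((spikes >= t0) & (spikes <= t1)).sum()
            n_surr = ((out >= t0) & (out <= t1)).sum(axis=1)
            assert np.all(n_surr == n_data)

    def test_shuffled_times_stay_in_window(self, rng):
        spikes = np.sort(rng.uniform(10, 20, 50))
        out = rigid_shuffle_times(spikes, [(10.0, 20.0)], 20, rng)
        assert out.min() >= 10.0 and out.max() <= 20.0

    def test_isi_preserved_up_to_wrap(self, rng):
        # ISI histogram within a flight is invariant modulo the wrap
        spikes = np.sort(rng.uniform(0, 10, 40))
        out = rigid_shuffle_times(spikes, [(0.0, 10.0)], 1, rng)[0]
        d_data = np.sort((spikes[None, :] - spikes[:, None]) % 10.0, axis=None)
        d_surr = np.sort((out[None, :] - out[:, None]) % 10.0, axis=None)
        assert np.allclose(d_data, d_surr, atol=1e-9)

    def test_spikes_outside_windows_untouched(self, rng):
        spikes = np.array([5.0, 50.0])
        out = rigid_shuffle_times(spikes, [(0.0, 10.0)], 5, rng)
        assert np.all(out[:, 1] == 50.0)


class TestSoloProjection:
    def test_projection_interpolation_identity(self, small_session, rng):
        # a solo spike at position x maps to the cross-over's d at that x
        cross = small_session["cross_pos"]
        solo = small_session["solo_pos"]
        c = cross[0]
        mid = c.x[len(c.x) // 2]
        d_expected = np.interp(mid, c.x[np.argsort(c.x)], c.d[np.argsort(c.x)])
        ens = solo_projection_shuffle(np.array([]), [c], solo, 3, rng)
        assert ens.kind == "solo_projection"
        # interpolation oracle applied directly
        assert d_expected == pytest.approx(
            np.interp(mid, np.sort(c.x), c.d[np.argsort(c.x)]))

    def test_position_marginal_preserved(self, small_session, rng):
        # each surrogate's spikes sit exactly at sampled solo spike positions
        cross = small_session["cross_pos"]
        solo = small_session["solo_pos"]
        cell = make_profiled_cell(5, None)
        spikes = simulate_spikes(cell, small_session["session"], 0,
                                 np.random.default_rng(6))
        pools = solo_pools(cross, solo)
        assert all(len(p) > 0 for p in pools)
        ens = solo_projection_shuffle(spikes, cross, solo, 5, rng)
        for sd in ens.spike_d:
            assert np.all(np.abs(sd) <= 40.0 + 1e-9)

    def test_pool_requires_same_direction_and_coverage(self, small_session):
        cross = small_session["cross_pos"]
        solo_wrong_dir = [s for s in small_session["solo_pos"]][:0]
        pools = solo_pools(cross, solo_wrong_dir)
        assert all(len(p) == 0 for p in pools)


class TestSignificantBins:
    def _ensemble(self, rates, valid=None, edges=None):
        nb = rates.shape[1]
        edges = edges if edges is not None else np.linspace(-40, 40, nb + 1)
        valid = valid if valid is not None else np.ones(nb, bool)
        return ShuffleEnsemble(kind="rigid", rates=rates, valid=valid, edges=edges)

    def test_data_identical_to_surrogates_nothing_flagged(self):
        rates = np.tile(np.linspace(1, 2, 40), (200, 1))
        ens = self._ensemble(rates)
        res = significant_bins(rates[0], ens, ens, mode="full_1d")
        assert not res.any_significant

    def test_isolated_bin_deflagged(self):
        rng = np.random.default_rng(0)
        base = rng.random((300, 40))
        data = base[0].copy() * 0 + 0.5
        data[20] = 10.0                    # one isolated super-threshold bin
        ens = self._ensemble(base)
        res = significant_bins(data, ens, ens, mode="full_1d")
        assert res.flags[20] == 0
        assert not res.any_significant

    def test_adjacent_pair_flagged_and_edges_removed(self):
        rng = np.random.default_rng(1)
        base = rng.random((300, 40))
        data = np.full(40, 0.5)
        data[[20, 21]] = 10.0
        data[[0, 39]] = 10.0               # edges must be deflagged
        ens = self._ensemble(base)
        res = significant_bins(data, ens, ens, mode="full_1d")
        assert res.flags[20] == 1 and res.flags[21] == 1
        assert res.flags[0] == 0 and res.flags[39] == 0
        assert res.runs == [(20, 22, 1)]

    def test_suppression_polarity(self):
        rng = np.random.default_rng(2)
        base = rng.random((300, 40)) + 1.0
        data = np.full(40, 1.5)
        data[[10, 11, 12]] = 0.0
        ens = self._ensemble(base)
        res = significant_bins(data, ens, ens, mode="full_1d")
        assert np.all(res.flags[[10, 11, 12]] == -1)

    def test_requires_both_ensembles_full_mode(self):
        rates = np.random.default_rng(3).random((200, 40))
        ens = self._ensemble(rates)
        with pytest.raises(ValueError, match="both"):
            significant_bins(rates[0], ens, None, mode="full_1d")

    def test_small_ensemble_refused(self):
        rates = np.random.default_rng(4).random((50, 40))
        ens = self._ensemble(rates)
        with pytest.raises(ValueError, match="too small"):
            significant_bins(rates[0], ens, ens, mode="full_1d")

    def test_field_level_mixed_thresholds(self):
        rng = np.random.default_rng(5)
        strict = rng.random((300, 30))          # data clearly beyond this one
        loose = rng.random((300, 30)) * 5.0     # data at ~85th percentile here
        data = np.full(30, 4.2)
        data[:] = np.nanpercentile(loose, 80, axis=0)
        data[[14, 15]] = 20.0
        ens_a = self._ensemble(strict)
        ens_b = self._ensemble(loose)
        res = significant_bins(data, ens_a, ens_b, mode="field_level")
        assert res.flags[14] == 1 and res.flags[15] == 1


class TestClassifyDistanceCell:
    def test_too_few_crossovers(self, small_session, rng):
        res = classify_distance_cell(np.array([1.0]),
                                     small_session["cross_pos"][:5],
                                     small_session["solo_pos"],
                                     n_shuffle=150, rng=rng)
        assert not res.is_distance_cell
        assert res.reason == "lt_10_crossovers"

    def test_thirty_spike_rule(self, big_session, rng):
        # a cell with < 30 cross-over spikes is never classified
        cross = big_session["cross_pos"]
        spikes = np.array([c.t_cross for c in cross[:25]])  # 25 spikes
        res = classify_distance_cell(spikes, cross, big_session["solo_pos"],
                                     n_shuffle=150, rng=rng)
        assert not res.is_distance_cell
        assert "lt_30_spikes" in res.reason

    def test_modulated_cell_detected(self, big_session):
        prof = DistanceProfile("enhance", center=-10.0, width=8.0, gain=4.0)
        cell = make_profiled_cell(101, prof)
        spikes = simulate_spikes(cell, big_session["session"], 0,
                                 np.random.default_rng(201))
        res = classify_distance_cell(spikes, big_session["cross_pos"],
                                     big_session["solo_pos"],
                                     n_shuffle=200, rng=np.random.default_rng(301))
        assert res.is_distance_cell
        # onset within [center - width, center + width/2]
        assert -18.0 <= res.significance.onset <= -6.0


class TestOddEvenStability:
    def test_zero_variance_returns_nan(self, small_session):
        r = odd_even_stability(np.array([]), small_session["cross_pos"])
        assert np.isnan(r)

    def test_modulated_cell_stable(self, big_session):
        # genuine distance structure reproduces across odd/even flight halves
        prof = DistanceProfile("enhance", center=-10.0, width=8.0, gain=4.0)
        cell = make_profiled_cell(7, prof)
        spikes = simulate_spikes(cell, big_session["session"], 0,
                                 np.random.default_rng(8))
        r = odd_even_stability(spikes, big_session["cross_pos"])
        assert r > 0.3


class TestSwitchTimes:
    def test_step_enhancement_fast_rise(self):
        t = np.arange(30) * 0.25            # time-to-crossover axis
        med = np.full(30, 1.0)
        data = np.full(30, 0.8)
        data[10:13] = 3.0                   # sharp 3-bin step
        flags = np.zeros(30, int)
        flags[10:13] = 1
        st = switch_times(data, med, flags, t)
        assert st is not None
        assert st.polarity == "enhancement"
        assert st.rise_time <= 0.25 + 1e-9  # within one original bin

    def test_symmetric_bump_rise_equals_fall(self):
        t = np.arange(40) * 0.25
        med = np.full(40, 1.0)
        bump = np.exp(-0.5 * ((np.arange(40) - 20) / 4.0) ** 2)
        data = 0.5 + 3.0 * bump
        flags = np.zeros(40, int)
        flags[18:23] = 1
        st = switch_times(data, med, flags, t)
        assert st is not None
        assert abs(st.rise_time - st.fall_time) <= 0.25 / 10 * 2 + 1e-9

    def test_never_crossing_median_excluded(self):
        t = np.arange(20) * 0.25
        med = np.full(20, 1.0)
        data = np.full(20, 2.0)             # always above the median
        flags = np.zeros(20, int)
        flags[8:10] = 1
        assert switch_times(data, med, flags, t) is None

    def test_mixed_polarity_excluded(self):
        t = np.arange(20) * 0.25
        flags = np.zeros(20, int)
        flags[3:5] = 1
        flags[12:14] = -1
        assert switch_times(np.ones(20), np.ones(20), flags, t) is None
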