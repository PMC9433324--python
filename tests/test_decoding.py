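import numpy as np
import pandas as pd
import pytest

from crossmap.decoding import (
    ml_decode_session,
    nonsep_experiment,
    sim_decode,
    summarize_decoding,
    tuning_change_profile,
)
from crossmap.synth.model import (
    ModelMap2D,
    NeuronModelConfig,
    TrialSimConfig,
    build_population,
    expected_counts_grid,
)
from crossmap.utils import bin_centers, bin_edges

from conftest import make_profiled_cell


def flat_map(value=1.0, m0=5.0):
    pos_edges = bin_edges(0.0, 130.0, 0.5)
    dist_edges = bin_edges(-40.0, 40.0, 0.5)
    grid = np.full((pos_edges.size - 1, dist_edges.size - 1), value)
    return ModelMap2D(rate_grid=grid, pos_edges=pos_edges, dist_edges=dist_edges,
                      fields=[(0.0, 130.0, 0)], m0=m0)


def localized_population(rng, n=100, sigma_d=4.0, sigma_p=8.0):
    """Neurons with sharp 2D bumps tiling the (d, p) space — high-information."""
    maps = []
    pos_edges = bin_edges(0.0, 130.0, 0.5)
    dist_edges = bin_edges(-40.0, 40.0, 0.5)
    pc = bin_centers(pos_edges)
    dc = bin_centers(dist_edges)
    for _ in range(n):
        d0 = rng.uniform(-40, 40)
        p0 = rng.uniform(0, 130)
        grid = 20.0 * np.outer(np.exp(-0.5 * ((pc - p0) / sigma_p) ** 2),
                               np.exp(-0.5 * ((dc - d0) / sigma_d) ** 2))
        maps.append(ModelMap2D(rate_grid=grid, pos_edges=pos_edges,
                               dist_edges=dist_edges, fields=[(0.0, 130.0, 0)],
                               m0=5.0))
    return maps


class TestSimDecode:
    def test_grid_is_451_combinations(self, rng):
        t = TrialSimConfig(n_repeats=1)
        res = sim_decode([flat_map()], t, rng)
        assert res.n_trials == 451

    def test_noiseless_highrate_population_decodes_to_grid_bin(self, rng):
        # decoder consistency oracle: sharp high-rate tunings, 100 cells, and
        # a short window so the path-midpoint offset stays below a grid step
        maps = localized_population(rng)
        for m in maps:
            m.m0 = 50.0
        t = TrialSimConfig(n_repeats=1, delta_t=0.05)
        res = sim_decode(maps, t, rng)
        assert np.median(res.err_d) <= 2.0     # one distance grid step
        assert np.median(res.err_x) <= 13.0    # one position grid step

    def test_path_midpoint_offset_with_long_window(self, rng):
        # with the standard 500 ms window the decoded start shifts by about the
        # path midpoint (+4 m distance, +2 m position) — a known approximation
        maps = localized_population(rng)
        for m in maps:
            m.m0 = 50.0
        res = sim_decode(maps, TrialSimConfig(n_repeats=1), rng)
        assert np.median(res.err_d) <= 6.0

    def test_ml_equals_pv_when_coverage_constant(self, rng):
        # flat total coverage -> the coverage term is constant -> identical
        maps = localized_population(rng, n=40)
        total = sum(m.rate_grid for m in maps)
        maps.append(flat_map())
        maps[-1].rate_grid = np.maximum(total.max() + 1.0 - total, 0.0)
        t = TrialSimConfig(n_repeats=2)
        seed_ml = np.random.default_rng(123)
        seed_pv = np.random.default_rng(123)
        res_ml = sim_decode(maps, t, seed_ml, decoder="ML")
        res_pv = sim_decode(maps, t, seed_pv, decoder="PV")
        assert np.array_equal(res_ml.err_d, res_pv.err_d)

    def test_catastrophic_geq_mean(self, rng):
        maps = build_population(NeuronModelConfig(x_sep=0.6), 20, rng)
        res = sim_decode(maps, TrialSimConfig(n_repeats=2), rng)
        assert res.catastrophic_distance_error >= res.mean_distance_error

    def test_all_zero_population_rejected(self, rng):
        m = flat_map(0.0)
        with pytest.raises(ValueError, match="zero"):
            sim_decode([m], TrialSimConfig(n_repeats=1), rng)

    def test_error_decreases_with_population_size(self, rng):
        t = TrialSimConfig(n_repeats=2)
        errs = []
        for N in (20, 60, 100):
            means = []
            for _ in range(4):
                maps = build_population(NeuronModelConfig(x_sep=0.6), N, rng)
                means.append(sim_decode(maps, t, rng).mean_distance_error)
            errs.append(np.mean(means))
        assert errs[0] > errs[1] > errs[2]


class TestLogLikelihoodAdditivity:
    def test_concatenated_population_identity(self, rng):
        # A(cells A u B) computed jointly equals the sum of group terms
        maps_a = localized_population(rng, n=5)
        maps_b = localized_population(rng, n=7)
        t = TrialSimConfig(n_repeats=1)
        Ma = expected_counts_grid(maps_a, t)
        Mb = expected_counts_grid(maps_b, t)
        Mab = expected_counts_grid(maps_a + maps_b, t)
        assert np.allclose(Mab, np.concatenate([Ma, Mb], axis=1))
        counts = rng.poisson(Mab)
        dd, pp = np.meshgrid(t.x0D_grid, t.x0P_grid, indexing="ij")
        F = np.stack([m.lookup(dd.ravel(), pp.ravel()) for m in maps_a + maps_b],
                     axis=1)
        logF = np.log(np.clip(5.0 * F, 1e-3, None))
        A_joint = counts @ logF.T - 5.0 * F.sum(axis=1)[None, :]
        A_split = (counts[:, :5] @ logF[:, :5].T - 5.0 * F[:, :5].sum(axis=1)[None, :]
                   + counts[:, 5:] @ logF[:, 5:].T - 5.0 * F[:, 5:].sum(axis=1)[None, :])
        assert np.allclose(A_joint, A_split)


class TestNonsepExperiment:
    def test_output_structure_and_invariants(self, rng):
        df = nonsep_experiment(x_sep_levels=(0.2, 1.0), N_grid=(20,),
                               n_populations=3, n_repeats=2, rng=rng,
                               compute_indices=False)
        assert len(df) == 6
        assert (df.cat_err_d >= df.mean_err_d - 1e-9).all()
        assert (df.cat_err_d_central >= df.mean_err_d_central - 1e-9).all()

    def test_lambda_alpha_recorded_when_requested(self, rng):
        df = nonsep_experiment(x_sep_levels=(1.0,), N_grid=(20,),
                               n_populations=2, n_repeats=1, rng=rng,
                               compute_indices=True)
        assert np.isfinite(df.alpha).all()
        assert (df.alpha > 0).all()


class TestSessionDecoding:
    def test_requires_ten_cells(self, small_session):
        with pytest.raises(ValueError, match=">= 10 cells"):
            ml_decode_session([np.array([])] * 5, small_session["cross_pos"])

    def test_synthetic_session_decodes_above_chance(self, big_session):
        rng = np.random.default_rng(77)
        cells = [make_profiled_cell(800 + i, None) for i in range(12)]
        from crossmap.synth import simulate_spikes

        spikes = [simulate_spikes(c, big_session["session"], 0,
                                  np.random.default_rng(900 + i))
                  for i, c in enumerate(cells)]
        cross = big_session["cross_pos"][:20]
        res = ml_decode_session(spikes, cross)
        assert len(res.windows) > 50
        summary = summarize_decoding(res, rng=rng)
        # position is strongly coded -> beats its behavioural chance level
        assert res.median_position_error < summary.chance_error_x

    def test_summary_quartiles(self):
        win = pd.DataFrame({
            "flight": np.repeat(np.arange(8), 5),
            "t": np.arange(40.0),
            "actual_d": np.random.default_rng(0).uniform(-30, 30, 40),
            "actual_x": np.random.default_rng(1).uniform(10, 120, 40),
            "dec_d": np.random.default_rng(2).uniform(-30, 30, 40),
            "dec_x": np.random.default_rng(3).uniform(10, 120, 40),
        })
        win["err_d"] = (win.dec_d - win.actual_d).abs()
        win["err_x"] = (win.dec_x - win.actual_x).abs()
        from crossmap.decoding import DecodeResult

        res = DecodeResult(windows=win, grid_d=np.arange(-40, 41, 3.0),
                           grid_x=np.arange(0, 136, 3.0))
        rates = np.linspace(1.0, 8.0, 8)
        s = summarize_decoding(res, flight_click_rates=rates,
                               rng=np.random.default_rng(4),
                               d_edges=np.arange(-40.5, 41, 3.0))
        assert s.quartile_errors is not None
        assert set(s.quartile_errors.index) <= {"q1", "q2", "q3", "q4"}
        assert s.confusion_d is not None

    def test_perfect_decoding_zero_error_confusion_diagonalish(self):
        actual = np.random.default_rng(5).uniform(-39, 39, 60)
        win = pd.DataFrame({
            "flight": 0, "t": np.arange(60.0),
            "actual_d": actual, "actual_x": 50.0,
            "dec_d": actual, "dec_x": 50.0,
            "err_d": 0.0, "err_x": 0.0,
        })
        from crossmap.decoding import DecodeResult

        res = DecodeResult(windows=win, grid_d=np.arange(-40, 41, 3.0),
                           grid_x=np.arange(0, 136, 3.0))
        s = summarize_decoding(res, rng=np.random.default_rng(6),
                               d_edges=np.arange(-40.5, 41, 3.0))
        # all mass on the diagonal after chance normalisation
        offdiag = s.confusion_d - np.diag(np.diag(s.confusion_d))
        assert np.allclose(offdiag, 0.0)


class TestTuningChangeProfile:
    def test_unmodulated_population_flat_correlation(self, big_session):
        from crossmap.synth import simulate_spikes
        from crossmap.tuning import position_tuning

        cells = [make_profiled_cell(30 + i, None) for i in range(5)]
        spikes, solos = [], []
        table = big_session["table"]
        traj = big_session["trajs"][0]
        solo_segs = table.solo_segments(0)
        for i, c in enumerate(cells):
            s = simulate_spikes(c, big_session["session"], 0,
                                np.random.default_rng(40 + i))
            spikes.append(s)
            solo_x, behav_x = [], []
            for _, seg in solo_segs[solo_segs.direction == 1].iterrows():
                sel = (s >= seg.t_start) & (s <= seg.t_end)
                solo_x.append(np.interp(s[sel], traj.t, traj.x))
                behav_x.append(traj.x[int(seg.i_start):int(seg.i_stop)])
            solos.append(position_tuning(np.concatenate(solo_x),
                                         np.concatenate(behav_x)))
        prof = tuning_change_profile(spikes, big_session["cross_pos"], solos,
                                     min_occ=0.2)
        ok = prof.dropna(subset=["corr"])
        assert len(ok) > 10
        # place code carries over to cross-overs: strong positive correlation
        assert ok["corr"].mean() > 0.5
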