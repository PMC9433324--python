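import numpy as np
import pytest

from crossmap.maps2d import RateMap2D
from crossmap.svd import (
    AdmissibilityError,
    SVDMatrix,
    cv_dimensionality,
    fit_lambda,
    multiplied_map,
    prepare_matrix,
    separability_indices,
    separability_significance,
)


def as_ratemap(rate, occupancy=None, spikes=None):
    rate = np.asarray(rate, dtype=float)
    occ = occupancy if occupancy is not None else np.full(rate.shape, 1.0)
    spk = spikes if spikes is not None else np.full(rate.shape, 5.0)
    rows, cols = rate.shape
    return RateMap2D(rate=rate, spikes=spk, occupancy=occ,
                     valid=np.isfinite(rate),
                     pos_edges=np.arange(rows + 1, dtype=float) * 3.0,
                     dist_edges=np.arange(cols + 1, dtype=float) * 3.0 - 40.5)


def random_low_rank(rng, rows=20, cols=27, rank=1):
    U = rng.random((rows, rank)) + 0.5
    V = rng.random((cols, rank)) + 0.5
    return U @ V.T


class TestSeparabilityIndices:
    def test_outer_product_alpha_zero(self, rng):
        M = np.outer(rng.random(15) + 0.5, rng.random(20) + 0.5)
        res = separability_indices(M, mean_subtract=False)
        assert res.alpha == pytest.approx(0.0, abs=1e-12)

    def test_identity_2x2_alpha_half(self):
        # s = [1, 1] -> alpha = 1 - 1/2 = 0.5
        res = separability_indices(np.eye(2), mean_subtract=False)
        assert np.allclose(res.singular_values, [1.0, 1.0])
        assert res.alpha == pytest.approx(0.5)

    def test_exact_exponential_lambda_recovery(self):
        # s_j = a * exp(-j / 3) -> fitted lambda = 3
        s = 2.0 * np.exp(-np.arange(1, 11) / 3.0)
        assert fit_lambda(s) == pytest.approx(3.0, rel=1e-9)

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            separability_indices(np.zeros((5, 5)))

    def test_incomplete_matrix_raises(self):
        M = np.ones((4, 4))
        M[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            separability_indices(M)

    def test_lambda_alpha_rank_correlated(self, rng):
        # the two indices order smooth-spectrum matrices consistently
        from scipy.stats import spearmanr

        lams, alphas = [], []
        for k in range(60):
            decay = rng.uniform(0.15, 0.85)      # geometric spectrum weight
            M = sum(decay ** j * np.outer(rng.standard_normal(20),
                                          rng.standard_normal(27))
                    for j in range(8))
            r = separability_indices(M, mean_subtract=False)
            lams.append(min(r.lam, 1e6))
            alphas.append(r.alpha)
        rho = spearmanr(lams, alphas).statistic
        assert rho > 0.8


class TestPrepareMatrix:
    def test_complete_matrix_identity(self, rng):
        rate = random_low_rank(rng)
        m = prepare_matrix(as_ratemap(rate), enforce_admissibility=False)
        assert m.n_iterations == 0
        assert np.array_equal(m.M, rate)

    def test_rank1_completion_recovers_deleted_entries(self, rng):
        # low-rank completion oracle: with the fill rank matched to the true
        # rank, the iterative reconstruction restores the deleted entries
        rate = random_low_rank(rng, rank=1)
        holes = rng.random(rate.shape) < 0.05
        rate_obs = rate.copy()
        rate_obs[holes] = np.nan
        m = prepare_matrix(as_ratemap(rate_obs), enforce_admissibility=False,
                           fill_rank=1)
        rel = np.abs(m.M[holes] - rate[holes]) / rate[holes]
        assert np.nanmax(rel) < 0.01

    def test_row_below_80pct_dropped(self, rng):
        rate = random_low_rank(rng)
        rate[3, :10] = np.nan               # 10/27 missing -> 63% valid
        m = prepare_matrix(as_ratemap(rate), enforce_admissibility=False)
        # the largest contiguous block excludes row 3
        assert m.M.shape[0] < rate.shape[0]

    def test_admissibility_extent(self, rng):
        rate = random_low_rank(rng, rows=10)     # 30 m < 45 m
        with pytest.raises(AdmissibilityError, match="extent"):
            prepare_matrix(as_ratemap(rate),
                           crossover_positions=np.linspace(0, 30, 20))

    def test_admissibility_crossover_gap(self, rng):
        rate = random_low_rank(rng, rows=20)     # 60 m extent
        xs = np.concatenate([np.linspace(0, 20, 10), np.linspace(45, 60, 10)])
        with pytest.raises(AdmissibilityError, match="gap"):
            prepare_matrix(as_ratemap(rate), crossover_positions=xs)


class TestMultipliedMap:
    def test_separable_by_construction(self, rng):
        shuffle = np.outer(rng.random(20) + 0.5, np.ones(27))
        tuning = rng.random(40) + 0.5
        centers = np.linspace(-39, 39, 40)
        col_edges = np.arange(28.0) * 3.0 - 40.5
        mm = multiplied_map(shuffle, tuning, centers, col_edges)
        res = separability_indices(mm, mean_subtract=False)
        assert res.alpha == pytest.approx(0.0, abs=1e-12)

    def test_rate_scale_preserved(self, rng):
        shuffle = rng.random((20, 27)) + 1.0
        tuning = np.full(40, 3.0)                # flat tuning, mean-normalised
        mm = multiplied_map(shuffle, tuning, np.linspace(-39, 39, 40),
                            np.arange(28.0) * 3.0 - 40.5)
        assert np.allclose(mm, shuffle)


class TestSeparabilitySignificance:
    def _nulls(self, rng, n=120, rows=20, cols=27):
        # position-only shuffle maps: rank-1 plus smoothed spiking noise,
        # mimicking how real shuffle maps are Gaussian-smoothed
        from scipy.ndimage import gaussian_filter

        out = []
        for _ in range(n):
            base = np.outer(rng.random(rows) + 0.5, np.ones(cols))
            noise = gaussian_filter(rng.normal(0, 0.3, (rows, cols)), 1.5)
            out.append(np.clip(base + noise, 0.0, None))
        return out

    def test_separable_cell_not_flagged(self, rng):
        rate = random_low_rank(rng, rank=1)
        data = prepare_matrix(as_ratemap(rate), enforce_admissibility=False)
        tuning = np.ones(40)
        flags = separability_significance(
            data, self._nulls(rng), tuning, np.linspace(-39, 39, 40),
            projection_dimension=0.1)
        assert not flags.non_separable     # rounded projection dim 0

    def test_opposite_polarity_two_field_cell_flagged(self):
        # end-to-end: a model cell whose two fields carry opposite-polarity
        # distance profiles is flagged against its multiplied-map null
        from crossmap.svd import model_cell_separability
        from crossmap.synth.model import (DistanceProfile, NeuronModelConfig,
                                          build_neuron_map)
        from crossmap.utils import bin_centers as centers_of

        m = build_neuron_map(NeuronModelConfig(x_sep=1.0),
                             np.random.default_rng(500))
        pc = centers_of(m.pos_edges)
        dc = centers_of(m.dist_edges)
        grid = np.zeros_like(m.rate_grid)
        pe = DistanceProfile("enhance", center=-10, width=10, gain=4.0)
        ps = DistanceProfile("suppress", center=-10, width=10, gain=0.05)
        (lo1, hi1, _), (lo2, hi2, _) = sorted(m.fields)[:2]
        grid[(pc >= lo1) & (pc < hi1), :] = pe.evaluate(dc)[None, :]
        grid[(pc >= lo2) & (pc < hi2), :] = ps.evaluate(dc)[None, :]
        m.rate_grid = grid
        m.hotspot = None
        m.fields = [(lo1, hi1, 0), (lo2, hi2, 1)]
        flags = model_cell_separability(m, np.random.default_rng(600),
                                        n_null=120)
        assert flags.non_separable

    def test_shared_profile_cell_not_flagged_mostly(self):
        from crossmap.svd import model_cell_separability
        from crossmap.synth.model import NeuronModelConfig, build_neuron_map

        rng = np.random.default_rng(1)
        flagged = [model_cell_separability(
            build_neuron_map(NeuronModelConfig(x_sep=0.2), rng), rng,
            n_null=110).non_separable for _ in range(10)]
        assert np.mean(flagged) <= 0.2

    def test_data_equal_multiplied_map_not_flagged(self, rng):
        tuning = np.linspace(0.5, 2.0, 40)
        centers = np.linspace(-39, 39, 40)
        col_edges = np.arange(28.0) * 3.0 - 40.5
        base = np.outer(rng.random(20) + 0.5, np.ones(27))
        rate = multiplied_map(base, tuning, centers, col_edges)
        data = prepare_matrix(as_ratemap(rate), enforce_admissibility=False)
        nulls = [np.outer(rng.random(20) + 0.5, np.ones(27)) for _ in range(120)]
        flags = separability_significance(data, nulls, tuning, centers,
                                          projection_dimension=2.0)
        # its multiplied-map nulls have the same structure -> percentile low
        assert not (flags.lam_percentile > 0.95 and flags.alpha_percentile > 0.95)

    def test_refuses_few_nulls(self, rng):
        data = prepare_matrix(as_ratemap(random_low_rank(rng)),
                              enforce_admissibility=False)
        with pytest.raises(ValueError, match="null maps"):
            separability_significance(data, self._nulls(rng, n=20), np.ones(40),
                                      np.linspace(-39, 39, 40), 1.0)


class TestCVDimensionality:
    def test_rank2_matrix_dimension_two(self, rng):
        M = random_low_rank(rng, rank=2)
        sm = SVDMatrix(M=M, row_edges=np.arange(21.0), col_edges=np.arange(28.0),
                       filled=np.zeros(M.shape, bool), n_iterations=0,
                       final_ssd=0.0)
        res = cv_dimensionality(sm, sm, n_iter=40, rng=rng, max_dim=6)
        # grand-mean subtraction can add one dimension to a rank-2 matrix
        assert res.meaningful_dimension in (2, 3)
        assert res.test_error[res.meaningful_dimension - 1] == min(res.test_error)

    def test_identical_maps_projection_dimension_zero(self, rng):
        M = random_low_rank(rng, rank=2) + rng.normal(0, 0.02, (20, 27))
        sm = SVDMatrix(M=M, row_edges=np.arange(21.0), col_edges=np.arange(28.0),
                       filled=np.zeros(M.shape, bool), n_iterations=0,
                       final_ssd=0.0)
        res = cv_dimensionality(sm, sm, n_iter=30, rng=rng, max_dim=5)
        assert res.projection_dimension == pytest.approx(0.0, abs=1e-9)

    def test_noise_turns_test_error_up(self, rng):
        M = random_low_rank(rng, rank=2) + rng.normal(0, 0.15, (20, 27))
        sm = SVDMatrix(M=M, row_edges=np.arange(21.0), col_edges=np.arange(28.0),
                       filled=np.zeros(M.shape, bool), n_iterations=0,
                       final_ssd=0.0)
        res = cv_dimensionality(sm, sm, n_iter=40, rng=rng, max_dim=8)
        k = res.meaningful_dimension
        assert k < 8
        assert res.test_error[-1] > res.test_error[k - 1]
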