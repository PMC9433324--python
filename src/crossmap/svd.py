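"""SVD-based non-separability of 2D distance-by-position maps.

A perfectly separable map is rank one: position profile x distance profile.
Two indices quantify the departure from separability: lambda, the decay
constant of an exponential fitted to the singular values, and alpha, the
fraction of variance not captured by the first singular value. Significance
is assessed against "multiplied maps": solo-projection shuffle maps whose
rows are scaled by the cell's 1D distance tuning — same behaviour, same spike
statistics, same 1D tuning, but separable by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .maps2d import RateMap2D
from .utils import as_rng, bin_centers

SSD_TOL = 1e-3
FILL_RANK = 10
MAX_FILL_ITER = 500
MIN_ROW_VALID_FRAC = 0.8
MIN_CROP_EXTENT = 45.0      # m of position
MAX_CROSS_GAP = 10.0        # m between adjacent cross-over positions
MIN_CROSSOVERS = 10
MIN_SPIKES = 30
MIN_PEAK = 2.0              # Hz


@dataclass
class SVDMatrix:
    """Cropped, completed rectangular rate matrix (position rows x distance cols)."""

    M: np.ndarray
    row_edges: np.ndarray           # position bin edges of the crop
    col_edges: np.ndarray
    filled: np.ndarray              # mask of originally-missing entries
    n_iterations: int
    final_ssd: float


class AdmissibilityError(ValueError):
    """Raised when a cell fails the coverage/spiking admissibility rules."""


def check_admissibility(map2d: RateMap2D, crossover_positions: np.ndarray,
                        row_sel: np.ndarray, n_spikes_crop: float) -> None:
    extent = row_sel.sum() * (map2d.pos_edges[1] - map2d.pos_edges[0])
    if extent < MIN_CROP_EXTENT:
        raise AdmissibilityError(f"cropped extent {extent:.1f} m < {MIN_CROP_EXTENT}")
    lo = map2d.pos_edges[:-1][row_sel][0]
    hi = map2d.pos_edges[1:][row_sel][-1]
    xs = np.sort(crossover_positions[(crossover_positions >= lo)
                                     & (crossover_positions <= hi)])
    if xs.size <= MIN_CROSSOVERS:
        raise AdmissibilityError(f"{xs.size} cross-overs in crop <= {MIN_CROSSOVERS}")
    gaps = np.diff(np.concatenate([[lo], xs, [hi]]))
    if gaps.max() >= MAX_CROSS_GAP:
        raise AdmissibilityError(f"position gap {gaps.max():.1f} m >= {MAX_CROSS_GAP}")
    if n_spikes_crop <= MIN_SPIKES:
        raise AdmissibilityError(f"{n_spikes_crop:.0f} spikes in crop <= {MIN_SPIKES}")


def _largest_valid_block(valid: np.ndarray) -> np.ndarray:
    """Row selector: largest contiguous block of rows with >= 80% valid columns."""
    row_ok = valid.mean(axis=1) >= MIN_ROW_VALID_FRAC
    best = (0, 0)
    i = 0
    while i < row_ok.size:
        if row_ok[i]:
            j = i
            while j < row_ok.size and row_ok[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    sel = np.zeros(row_ok.size, dtype=bool)
    sel[best[0]:best[1]] = True
    return sel


def _neighbour_fill(M: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Initialise missing entries from the mean of observed neighbours,
    growing outward until everything is filled."""
    from scipy import ndimage

    out = M.copy()
    known = ~missing
    while not known.all():
        vals = np.where(known, out, 0.0)
        num = ndimage.uniform_filter(vals, size=3, mode="constant") * 9.0
        den = ndimage.uniform_filter(known.astype(float), size=3, mode="constant") * 9.0
        newly = ~known & (den > 0)
        if not newly.any():
            out[~known] = np.nanmean(out[known]) if known.any() else 0.0
            break
        out[newly] = num[newly] / den[newly]
        known |= newly
    return out


def _rank_k(M: np.ndarray, k: int) -> np.ndarray:
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    k = min(k, s.size)
    return (U[:, :k] * s[:k]) @ Vt[:k]


def prepare_matrix(map2d: RateMap2D,
                   crossover_positions: np.ndarray | None = None,
                   enforce_admissibility: bool = True,
                   fill_rank: int = FILL_RANK) -> SVDMatrix:
    """Crop rows to >= 80% valid distance bins and complete missing entries.

    Missing bins are initialised from neighbour means, then iteratively
    replaced by rank-10 SVD reconstructions until the sum of squared changes
    drops below 1e-3. Already-complete matrices pass through unchanged.
    """
    valid = map2d.valid & np.isfinite(map2d.rate)
    row_sel = _largest_valid_block(valid)
    if not row_sel.any():
        raise AdmissibilityError("no rows with 80% valid distance bins")
    if enforce_admissibility:
        if crossover_positions is None:
            raise ValueError("crossover_positions required for admissibility checks")
        n_spk = float(map2d.spikes[row_sel].sum())
        check_admissibility(map2d, crossover_positions, row_sel, n_spk)
        peak = np.nanmax(map2d.rate[row_sel])
        if not peak > MIN_PEAK:
            raise AdmissibilityError(f"peak rate {peak:.2f} Hz <= {MIN_PEAK}")

    sub = map2d.rate[row_sel].copy()
    sub_valid = valid[row_sel]
    missing = ~sub_valid
    row_edges = np.concatenate([map2d.pos_edges[:-1][row_sel],
                                [map2d.pos_edges[1:][row_sel][-1]]])
    if not missing.any():
        return SVDMatrix(M=sub, row_edges=row_edges, col_edges=map2d.dist_edges,
                         filled=missing, n_iterations=0, final_ssd=0.0)

    M = _neighbour_fill(np.where(sub_valid, sub, np.nan), missing)
    ssd = np.inf
    it = 0
    while ssd >= SSD_TOL:
        it += 1
        if it > MAX_FILL_ITER:
            raise RuntimeError(f"matrix completion did not converge "
                               f"(SSD {ssd:.2e} after {MAX_FILL_ITER} iterations)")
        recon = _rank_k(M, fill_rank)
        new = M.copy()
        new[missing] = recon[missing]
        ssd = float(np.sum((new - M) ** 2))
        M = new
    return SVDMatrix(M=M, row_edges=row_edges, col_edges=map2d.dist_edges,
                     filled=missing, n_iterations=it, final_ssd=ssd)


@dataclass
class SeparabilityResult:
    singular_values: np.ndarray
    U: np.ndarray
    V: np.ndarray
    lam: float
    alpha: float


def fit_lambda(s: np.ndarray) -> float:
    """Decay constant of s_j = a * exp(-j / lambda), least squares in linear
    space over the whole spectrum.

    The linear-space fit is dominated by the leading singular values — the
    structured part of the spectrum — so lambda tracks how slowly variance
    leaves the top components (and co-varies tightly with alpha). A log-space
    fit would instead be ruled by the noise floor, whose flat tail carries
    enormous leverage in log units.
    """
    from scipy.optimize import curve_fit

    s = np.asarray(s, dtype=float)
    if s.size == 0:
        return np.nan
    if s.size == 1 or s[1] <= 0:
        return 0.0                            # immediate collapse
    j = np.arange(1, s.size + 1)
    # initialise from the two leading values: lambda0 = 1 / ln(s1/s2)
    ratio = s[0] / s[1]
    lam0 = 1.0 / np.log(ratio) if ratio > 1.0 else float(s.size)
    try:
        popt, _ = curve_fit(lambda x, a, lam: a * np.exp(-x / lam), j, s,
                            p0=[s[0] * np.exp(1.0 / lam0), lam0],
                            maxfev=10_000)
        lam = popt[1]
    except RuntimeError:
        lam = lam0
    if not np.isfinite(lam) or lam < 0:
        return np.inf
    return float(lam)


def separability_indices(M: np.ndarray | SVDMatrix,
                         mean_subtract: bool = True) -> SeparabilityResult:
    """Singular spectrum, lambda and alpha of a complete matrix."""
    A = M.M if isinstance(M, SVDMatrix) else np.asarray(M, dtype=float)
    if not np.isfinite(A).all():
        raise ValueError("matrix has missing entries; run prepare_matrix first")
    if np.allclose(A, 0.0):
        raise ValueError("all-zero matrix: separability undefined")
    if mean_subtract:
        A = A - A.mean()
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    alpha = float(1.0 - s[0] ** 2 / np.sum(s ** 2)) if s.size else np.nan
    return SeparabilityResult(singular_values=s, U=U, V=Vt.T,
                              lam=fit_lambda(s), alpha=alpha)


def multiplied_map(shuffle_matrix: np.ndarray, dist_tuning_rate: np.ndarray,
                   dist_tuning_centers: np.ndarray,
                   col_edges: np.ndarray) -> np.ndarray:
    """Scale each position row of a shuffle matrix by the cell's 1D distance
    tuning (resampled onto the matrix's distance columns, normalised to mean 1
    so the overall rate scale is preserved)."""
    centers = bin_centers(col_edges)
    ok = np.isfinite(dist_tuning_rate)
    prof = np.interp(centers, dist_tuning_centers[ok], dist_tuning_rate[ok])
    m = prof.mean()
    if m > 0:
        prof = prof / m
    return shuffle_matrix * prof[None, :]


@dataclass
class SeparabilityFlags:
    lam: float
    alpha: float
    lam_percentile: float
    alpha_percentile: float
    projection_dimension: float
    non_separable: bool


def separability_significance(data: SVDMatrix,
                              null_matrices: list[np.ndarray],
                              dist_tuning_rate: np.ndarray,
                              dist_tuning_centers: np.ndarray,
                              projection_dimension: float,
                              min_null: int = 100) -> SeparabilityFlags:
    """Flag a cell as non-separable: lambda AND alpha above the 95th null
    percentile AND rounded projection dimension >= 1."""
    if len(null_matrices) < min_null:
        raise ValueError(f"need >= {min_null} null maps, got {len(null_matrices)}")
    res = separability_indices(data)
    lams, alphas = [], []
    for nm in null_matrices:
        mm = multiplied_map(nm, dist_tuning_rate, dist_tuning_centers,
                            data.col_edges)
        try:
            r = separability_indices(mm)
        except ValueError:
            continue
        lams.append(r.lam)
        alphas.append(r.alpha)
    lams = np.asarray(lams)
    alphas = np.asarray(alphas)
    lam_pct = float((lams < res.lam).mean())
    alpha_pct = float((alphas < res.alpha).mean())
    # round half away from zero
    rounded = math.floor(projection_dimension + 0.5)
    flag = lam_pct > 0.95 and alpha_pct > 0.95 and rounded >= 1
    return SeparabilityFlags(lam=res.lam, alpha=res.alpha,
                             lam_percentile=lam_pct, alpha_percentile=alpha_pct,
                             projection_dimension=projection_dimension,
                             non_separable=bool(flag))


def model_cell_separability(map2d, rng, n_null: int = 150,
                            occ_per_bin: float = 1.5,
                            n_cv_iter: int = 20, max_dim: int = 6):
    """End-to-end separability test of one model neuron.

    Samples a Poisson-noised coarse 2D rate map of the cell, builds matched
    position-only null maps (same spiking statistics, no distance tuning),
    multiplies them by the cell's measured 1D distance tuning and applies the
    lambda/alpha/projection-dimension criteria. Returns SeparabilityFlags.
    """
    from .synth.session import coarse_hz_grids, sample_rate_map

    rng = as_rng(rng)
    hz2d, hz_pos = coarse_hz_grids(map2d)
    rows, cols = hz2d.shape
    data = sample_rate_map(hz2d, occ_per_bin, rng)
    nulls = [sample_rate_map(np.tile(hz_pos[:, None], (1, cols)),
                             occ_per_bin, rng) for _ in range(n_null)]
    dist_tuning = data.mean(axis=0)                 # uniform-occupancy marginal
    col_edges = map2d.dist_edges[0] + np.arange(cols + 1) * 3.0
    centers = bin_centers(col_edges)
    sm = SVDMatrix(M=data, row_edges=np.arange(rows + 1) * 3.0,
                   col_edges=col_edges, filled=np.zeros(data.shape, bool),
                   n_iterations=0, final_ssd=0.0)
    solo_median = np.median(np.stack(nulls), axis=0)
    cv = cv_dimensionality(sm, solo_median, n_iter=n_cv_iter, rng=rng,
                           max_dim=max_dim)
    return separability_significance(sm, nulls, dist_tuning, centers,
                                     projection_dimension=cv.projection_dimension,
                                     min_null=min(100, n_null))


@dataclass
class CVDimResult:
    meaningful_dimension: int
    meaningful_dimension_solo: int
    projection_dimension: float
    test_error: np.ndarray
    train_error: np.ndarray
    n_dropped: int = 0


def _cv_test_error(M: np.ndarray, n_iter: int, rng: np.random.Generator,
                   max_dim: int | None = None,
                   max_inner: int = 200) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean test/train MSE vs cumulative reconstruction dimension."""
    rows, cols = M.shape
    kmax = max_dim or min(rows, cols)
    n_bins = rows * cols
    n_test = max(1, int(round(0.1 * n_bins)))
    test_err = np.zeros(kmax)
    train_err = np.zeros(kmax)
    dropped = 0
    flat = M.ravel()
    grand = M.mean()
    for _ in range(n_iter):
        test_idx = rng.choice(n_bins, size=n_test, replace=False)
        test_mask = np.zeros(n_bins, dtype=bool)
        test_mask[test_idx] = True
        test_mask2d = test_mask.reshape(rows, cols)
        ok = True
        for k in range(1, kmax + 1):
            A = M.copy()
            A[test_mask2d] = grand
            ssd = np.inf
            inner = 0
            while ssd >= SSD_TOL:
                inner += 1
                if inner > max_inner:
                    ok = False
                    break
                recon = _rank_k(A, k)
                new = A.copy()
                new[test_mask2d] = recon[test_mask2d]
                ssd = float(np.sum((new - A) ** 2))
                A = new
            if not ok:
                break
            resid = (A.ravel() - flat) ** 2
            test_err[k - 1] += resid[test_mask].mean()
            train_recon = _rank_k(A, k)
            train_resid = (train_recon.ravel() - flat) ** 2
            train_err[k - 1] += train_resid[~test_mask].mean()
        if not ok:
            dropped += 1
    n_used = n_iter - dropped
    if n_used == 0:
        raise RuntimeError("all cross-validation iterations failed to converge")
    return test_err / n_used, train_err / n_used, dropped


def cv_dimensionality(data: SVDMatrix, solo_median: SVDMatrix | np.ndarray,
                      n_iter: int = 1000, rng=None,
                      max_dim: int | None = None) -> CVDimResult:
    """Cross-validated meaningful dimension and projection dimension.

    10% of bins are held out per iteration, re-estimated iteratively at each
    cumulative dimension, and scored by test MSE; the meaningful dimension is
    the argmin of the mean test error. The projection dimension removes the
    solo-median map's meaningful subspace from the data's meaningful vectors:
    ``min(sum ||U_p||^2, sum ||V_p||^2)``.
    """
    rng = as_rng(rng)
    Md = data.M
    Ms = solo_median.M if isinstance(solo_median, SVDMatrix) else np.asarray(solo_median)
    if Md.shape != Ms.shape:
        raise ValueError("data and solo-median matrices must share the grid")

    test_d, train_d, drop_d = _cv_test_error(Md - Md.mean(), n_iter, rng, max_dim)
    test_s, train_s, drop_s = _cv_test_error(Ms - Ms.mean(), n_iter, rng, max_dim)
    kd = int(np.argmin(test_d)) + 1
    ks = int(np.argmin(test_s)) + 1

    Ud, sd_, Vdt = np.linalg.svd(Md - Md.mean(), full_matrices=False)
    Us, ss_, Vst = np.linalg.svd(Ms - Ms.mean(), full_matrices=False)
    Ud, Vd = Ud[:, :kd], Vdt.T[:, :kd]
    Us, Vs = Us[:, :ks], Vst.T[:, :ks]
    Up = Ud - Us @ (Us.T @ Ud)
    Vp = Vd - Vs @ (Vs.T @ Vd)
    proj_dim = float(min(np.sum(Up ** 2), np.sum(Vp ** 2)))
    return CVDimResult(meaningful_dimension=kd, meaningful_dimension_solo=ks,
                       projection_dimension=proj_dim, test_error=test_d,
                       train_error=train_d, n_dropped=drop_d + drop_s)
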