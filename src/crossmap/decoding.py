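"""Bayesian decoding of interbat distance and position.

Two settings share the Poisson log-likelihood machinery:

* session decoding — leave-one-out over cross-over flights, tau = 1 s windows
  stepped by 250 ms, with a coverage-correction term and an occupancy prior;
* simulation decoding — ML (coverage term, no prior) and PV (activity-weighted
  log-tuning only) decoders on model populations over a 41 x 11 start grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import CrossoverFlight
from .maps2d import crossover_map
from .synth.model import ModelMap2D, TrialSimConfig, expected_counts_grid
from .tuning import TuningCurve1D
from .utils import as_rng, bin_centers

RATE_FLOOR = 1e-3            # Hz inside log terms
TAU = 1.0                    # s decoding window
STEP = 0.25                  # s window step


@dataclass
class DecodeResult:
    windows: pd.DataFrame    # flight, t, actual_d, actual_x, dec_d, dec_x, err_d, err_x
    grid_d: np.ndarray
    grid_x: np.ndarray
    n_skipped: int = 0

    @property
    def median_distance_error(self) -> float:
        return float(self.windows.err_d.median())

    @property
    def median_position_error(self) -> float:
        return float(self.windows.err_x.median())


def _window_counts(spike_times: np.ndarray, starts: np.ndarray,
                   tau: float) -> np.ndarray:
    lo = np.searchsorted(spike_times, starts)
    hi = np.searchsorted(spike_times, starts + tau)
    return (hi - lo).astype(float)


def ml_decode_session(cell_spikes: list[np.ndarray],
                      crossovers: list[CrossoverFlight],
                      model_source: str = "crossover_2d",
                      solo_tunings: list[TuningCurve1D] | None = None,
                      min_cells: int = 10,
                      tau: float = TAU, step: float = STEP) -> DecodeResult:
    """Leave-one-out simultaneous decoding of (distance, position).

    ``model_source='solo_1d'`` decodes position only, from the supplied solo
    position tunings (no cross-validation needed: solo data are disjoint from
    the decoded cross-over flights).
    """
    if len(cell_spikes) < min_cells:
        raise ValueError(f"session needs >= {min_cells} cells, got {len(cell_spikes)}")
    rows = []
    n_skipped = 0
    grid_d = grid_x = None

    if model_source == "solo_1d":
        if solo_tunings is None:
            raise ValueError("solo_1d decoding requires solo tunings")
        valid = np.logical_and.reduce([
            t.valid & np.isfinite(t.rate) for t in solo_tunings])
        centers = solo_tunings[0].centers
        if not valid.any():
            raise ValueError("no jointly valid position bins")
        F = np.stack([np.clip(t.rate[:], RATE_FLOOR, None) for t in solo_tunings])
        F = F[:, valid]
        logF = np.log(F)
        occ = np.zeros(valid.sum())
        for c in crossovers:
            idx = np.searchsorted(centers[valid], c.x)
            occ += np.bincount(np.clip(idx, 0, occ.size - 1), minlength=occ.size)
        prior = occ / occ.sum() if occ.sum() else np.full(occ.size, 1 / occ.size)
        log_prior = np.log(np.clip(prior, 1e-12, None))
        for fi, c in enumerate(crossovers):
            starts = np.arange(c.t[0], c.t[-1] - tau + 1e-9, step)
            if starts.size == 0:
                n_skipped += 1
                continue
            counts = np.stack([_window_counts(s, starts, tau) for s in cell_spikes])
            A = counts.T @ logF - tau * F.sum(axis=0)[None, :] + log_prior[None, :]
            best = np.argmax(A, axis=1)
            xs = centers[valid][best]
            mid = starts + tau / 2.0
            actual_x = np.interp(mid, c.t, c.x)
            actual_d = np.interp(mid, c.t, c.d)
            for t0, ax, ad, dx in zip(mid, actual_x, actual_d, xs):
                rows.append({"flight": fi, "t": t0, "actual_d": ad,
                             "actual_x": ax, "dec_d": np.nan, "dec_x": dx,
                             "err_d": np.nan, "err_x": abs(dx - ax)})
        win = pd.DataFrame(rows)
        return DecodeResult(windows=win, grid_d=np.array([]),
                            grid_x=centers[valid], n_skipped=n_skipped)

    for fi, test in enumerate(crossovers):
        train = [c for j, c in enumerate(crossovers) if j != fi]
        maps = [crossover_map(s, train) for s in cell_spikes]
        valid = np.logical_and.reduce([m.valid & np.isfinite(m.rate) for m in maps])
        occ = np.zeros(valid.shape)
        for m in maps[:1]:
            occ = m.occupancy
        valid &= occ > 0
        if not valid.any():
            n_skipped += 1
            continue
        pos_c = bin_centers(maps[0].pos_edges)
        dist_c = bin_centers(maps[0].dist_edges)
        rows_idx, cols_idx = np.nonzero(valid)
        F = np.stack([np.clip(m.rate[valid], RATE_FLOOR, None) for m in maps])
        logF = np.log(F)
        prior = occ[valid] / occ[valid].sum()
        log_prior = np.log(np.clip(prior, 1e-12, None))
        if grid_d is None:
            grid_d, grid_x = dist_c, pos_c

        starts = np.arange(test.t[0], test.t[-1] - tau + 1e-9, step)
        if starts.size == 0:
            n_skipped += 1
            continue
        counts = np.stack([_window_counts(s, starts, tau) for s in cell_spikes])
        A = counts.T @ logF - tau * F.sum(axis=0)[None, :] + log_prior[None, :]
        best = np.argmax(A, axis=1)
        dec_x = pos_c[rows_idx[best]]
        dec_d = dist_c[cols_idx[best]]
        mid = starts + tau / 2.0
        actual_x = np.interp(mid, test.t, test.x)
        actual_d = np.interp(mid, test.t, test.d)
        for t0, ax, ad, dx, dd in zip(mid, actual_x, actual_d, dec_x, dec_d):
            rows.append({"flight": fi, "t": t0, "actual_d": ad, "actual_x": ax,
                         "dec_d": dd, "dec_x": dx, "err_d": abs(dd - ad),
                         "err_x": abs(dx - ax)})
    win = pd.DataFrame(rows)
    return DecodeResult(windows=win,
                        grid_d=grid_d if grid_d is not None else np.array([]),
                        grid_x=grid_x if grid_x is not None else np.array([]),
                        n_skipped=n_skipped)


@dataclass
class DecodeSummary:
    confusion_d: np.ndarray | None
    confusion_x: np.ndarray | None
    chance_error_d: float
    chance_error_x: float
    quartile_errors: pd.DataFrame | None


def summarize_decoding(result: DecodeResult,
                       flight_click_rates: np.ndarray | None = None,
                       n_chance: int = 100, rng=None,
                       d_edges: np.ndarray | None = None,
                       x_edges: np.ndarray | None = None) -> DecodeSummary:
    """Confusion matrices (normalised to chance), behavioural chance error and
    click-rate-quartile error table."""
    rng = as_rng(rng)
    win = result.windows

    def _confusion(actual, decoded, edges):
        if edges is None or decoded.isna().all():
            return None
        nb = edges.size - 1
        ai = np.clip(np.searchsorted(edges, actual, side="right") - 1, 0, nb - 1)
        di = np.clip(np.searchsorted(edges, decoded, side="right") - 1, 0, nb - 1)
        M = np.zeros((nb, nb))
        np.add.at(M, (ai, di), 1.0)
        sums = M.sum(axis=1, keepdims=True)
        M = np.divide(M, sums, out=np.zeros_like(M), where=sums > 0)
        return M * nb          # divide by P_chance = 1 / n_bins

    conf_d = _confusion(win.actual_d, win.dec_d, d_edges) if len(win) else None
    conf_x = _confusion(win.actual_x, win.dec_x, x_edges) if len(win) else None

    def _chance(actual):
        vals = actual.to_numpy()
        if vals.size == 0:
            return np.nan
        draws = rng.choice(vals, size=(vals.size, n_chance), replace=True)
        return float(np.median(np.abs(draws - vals[:, None])))

    chance_d = _chance(win.actual_d.dropna()) if len(win) else np.nan
    chance_x = _chance(win.actual_x.dropna()) if len(win) else np.nan

    qtab = None
    if flight_click_rates is not None and len(win):
        rates = np.asarray(flight_click_rates, dtype=float)
        w = win.copy()
        w["click_rate"] = rates[w.flight.to_numpy()]
        w = w[np.isfinite(w.click_rate) & np.isfinite(w.err_d)]
        if len(w):
            w["quartile"] = pd.qcut(w.click_rate, 4, labels=["q1", "q2", "q3", "q4"],
                                    duplicates="drop")
            g = w.groupby("quartile", observed=True)["err_d"]
            qtab = pd.DataFrame({"mean": g.mean(), "sem": g.sem(), "n": g.size()})
    return DecodeSummary(confusion_d=conf_d, confusion_x=conf_x,
                         chance_error_d=chance_d, chance_error_x=chance_x,
                         quartile_errors=qtab)


def tuning_change_profile(cell_spikes: list[np.ndarray],
                          crossovers: list[CrossoverFlight],
                          solo_tunings: list[TuningCurve1D],
                          window: float = 10.0, step: float = 2.0,
                          d_range: float = 40.0,
                          min_occ: float | None = None) -> pd.DataFrame:
    """Per-distance-window change of the position code during cross-overs.

    For each 10 m sliding distance window (2 m steps): Pearson correlation of
    the within-window position tuning with the solo tuning, spatial
    information, and mean peak-normalised rate — averaged over cells.
    ``min_occ`` overrides the 0.8 s per-bin occupancy floor (small synthetic
    sessions have far less within-window coverage than the recorded ones).
    """
    from .tuning import (POSITION_MIN_OCC, POSITION_SIGMA_BINS, compute_tuning,
                         spatial_information)
    from .utils import gaussian_kernel_1d

    if min_occ is None:
        min_occ = POSITION_MIN_OCC
    kernel = gaussian_kernel_1d(POSITION_SIGMA_BINS)

    starts = np.arange(-d_range, d_range - window + 1e-9, step)
    recs = []
    behav_x = np.concatenate([c.x for c in crossovers])
    behav_d = np.concatenate([c.d for c in crossovers])
    for w0 in starts:
        w1 = w0 + window
        bsel = (behav_d >= w0) & (behav_d < w1)
        corrs, sis, rates = [], [], []
        for spikes, solo in zip(cell_spikes, solo_tunings):
            sx, sd = [], []
            for c in crossovers:
                sel = (spikes >= c.t[0]) & (spikes <= c.t[-1])
                ts = spikes[sel]
                d_spk = np.interp(ts, c.t, c.d)
                keep = (d_spk >= w0) & (d_spk < w1)
                sx.append(np.interp(ts[keep], c.t, c.x))
            sx = np.concatenate(sx) if sx else np.array([])
            curve = compute_tuning(sx, behav_x[bsel], solo.edges, min_occ,
                                   kernel, variable="position")
            ok = curve.valid & solo.valid & np.isfinite(curve.rate) & np.isfinite(solo.rate)
            if ok.sum() >= 5 and np.nanstd(curve.rate[ok]) > 0 \
                    and np.nanstd(solo.rate[ok]) > 0:
                corrs.append(float(np.corrcoef(curve.rate[ok], solo.rate[ok])[0, 1]))
            try:
                sis.append(spatial_information(curve.rate, curve.occupancy, curve.valid))
            except ValueError:
                pass
            peak = np.nanmax(solo.rate) if np.isfinite(solo.rate).any() else np.nan
            if peak and np.isfinite(peak) and ok.any():
                rates.append(float(np.nanmean(curve.rate[ok]) / peak))
        recs.append({"d_center": w0 + window / 2.0,
                     "corr": float(np.mean(corrs)) if corrs else np.nan,
                     "si": float(np.mean(sis)) if sis else np.nan,
                     "norm_rate": float(np.mean(rates)) if rates else np.nan,
                     "n_cells": len(corrs)})
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# simulation decoders


@dataclass
class SimDecodeResult:
    err_d: np.ndarray            # (n_trials_total,)
    err_x: np.ndarray
    true_d: np.ndarray           # aligned with err_d (repeats tiled)
    true_x: np.ndarray
    n_trials: int

    @property
    def mean_distance_error(self) -> float:
        return float(self.err_d.mean())

    @property
    def catastrophic_distance_error(self) -> float:
        return float(np.percentile(self.err_d, 99))

    def central(self, d_band: float = 20.0) -> np.ndarray:
        """Errors on trials starting inside |x0D| <= d_band, where the
        distance code is informative (the far tail rides the chance curve)."""
        return self.err_d[np.abs(self.true_d) <= d_band]


def sim_decode(maps: list[ModelMap2D], tcfg: TrialSimConfig, rng,
               decoder: str = "ML") -> SimDecodeResult:
    """Decode every (x0D, x0P) grid combination, ``n_repeats`` times.

    ML maximises ``sum n_i log(m0 f_i) - m0 sum f_i``; PV drops the coverage
    term. Candidate grid points where every neuron is silent are skipped.

    Exact likelihood ties (common at uninformative extreme distances, where
    whole stretches of candidates share identical tunings) are broken by a
    seeded uniform draw among the tied candidates: a positional rule would
    map the ambiguity systematically onto one grid edge and distort the
    error tail.
    """
    rng = as_rng(rng)
    m0 = maps[0].m0
    M = expected_counts_grid(maps, tcfg)                    # (n_trials, N)
    dd, pp = np.meshgrid(tcfg.x0D_grid, tcfg.x0P_grid, indexing="ij")
    true_d, true_x = dd.ravel(), pp.ravel()

    # candidate tunings evaluated at the grid points themselves
    F = np.stack([m.lookup(true_d, true_x) for m in maps], axis=1)  # (n_cand, N)
    cand_ok = F.sum(axis=1) > 0
    if not cand_ok.any():
        raise ValueError("all candidate tunings are zero")
    Fc = F[cand_ok]
    logF = np.log(np.clip(m0 * Fc, RATE_FLOOR, None))
    coverage = m0 * Fc.sum(axis=1)

    errs_d, errs_x = [], []
    for _ in range(tcfg.n_repeats):
        counts = rng.poisson(M)                              # (n_trials, N)
        A = counts @ logF.T
        if decoder == "ML":
            A = A - coverage[None, :]
        elif decoder != "PV":
            raise ValueError(f"unknown decoder {decoder!r}")
        Amax = A.max(axis=1, keepdims=True)
        tied = A == Amax
        n_tied = tied.sum(axis=1)
        best = np.argmax(A, axis=1)
        multi = np.flatnonzero(n_tied > 1)
        for i in multi:
            best[i] = rng.choice(np.flatnonzero(tied[i]))
        sel = np.flatnonzero(cand_ok)[best]
        errs_d.append(np.abs(true_d[sel] - true_d))
        errs_x.append(np.abs(true_x[sel] - true_x))
    reps = tcfg.n_repeats
    return SimDecodeResult(err_d=np.concatenate(errs_d),
                           err_x=np.concatenate(errs_x),
                           true_d=np.tile(true_d, reps),
                           true_x=np.tile(true_x, reps),
                           n_trials=true_d.size * reps)


def map_separability_indices(map2d: ModelMap2D, downsample: int = 4):
    """lambda and alpha of a model map, optionally on a coarsened grid."""
    from .svd import separability_indices

    g = map2d.rate_grid
    if downsample > 1:
        rows = (g.shape[0] // downsample) * downsample
        cols = (g.shape[1] // downsample) * downsample
        g = g[:rows, :cols].reshape(rows // downsample, downsample,
                                    cols // downsample, downsample).mean(axis=(1, 3))
    try:
        r = separability_indices(g)
        return r.lam, r.alpha
    except ValueError:
        return np.nan, np.nan


def nonsep_experiment(x_sep_levels: tuple[float, ...] = (0.2, 0.6, 1.0),
                      N_grid: tuple[int, ...] = (20, 60, 100),
                      n_populations: int = 25, n_repeats: int = 5,
                      rng=None, decoder: str = "ML",
                      compute_indices: bool = True,
                      tcfg: TrialSimConfig | None = None) -> pd.DataFrame:
    """Mean and catastrophic (99th-percentile) decoding error vs x_sep and N.

    One row per (x_sep, N, population): mean/catastrophic distance and
    position errors (overall and over the informative |x0D| <= 20 m band),
    plus population-median lambda and alpha for post-hoc regrouping.

    Populations are *matched* across x_sep levels — same field layouts and
    modulation draws, differing only in how the profiles are spread over the
    fields — and share the decoding noise stream, so per-population
    comparisons between levels are paired.
    """
    from .synth.model import NeuronModelConfig, build_matched_populations

    rng = as_rng(rng)
    cfg = NeuronModelConfig()
    rows = []
    t = tcfg or TrialSimConfig(n_repeats=n_repeats)
    if t.n_repeats != n_repeats:
        t = TrialSimConfig(n_repeats=n_repeats)
    for pop_id in range(n_populations):
        pops = build_matched_populations(cfg, tuple(x_sep_levels), max(N_grid),
                                         rng)
        decode_seeds = {N: rng.integers(2**63) for N in N_grid}
        for x_sep in x_sep_levels:
            maps = pops[x_sep]
            lam = alpha = np.nan
            if compute_indices:
                la = np.array([map_separability_indices(m) for m in maps])
                finite = np.isfinite(la).all(axis=1) & (la[:, 0] < np.inf)
                if finite.any():
                    lam = float(np.median(la[finite, 0]))
                    alpha = float(np.median(la[finite, 1]))
            for N in N_grid:
                res = sim_decode(maps[:N], t,
                                 np.random.default_rng(decode_seeds[N]),
                                 decoder=decoder)
                cen = res.central()
                rows.append({"x_sep": x_sep, "N": N, "population": pop_id,
                             "lam": lam, "alpha": alpha,
                             "mean_err_d": res.mean_distance_error,
                             "cat_err_d": res.catastrophic_distance_error,
                             "mean_err_d_central": float(cen.mean()),
                             "cat_err_d_central": float(np.percentile(cen, 99)),
                             "mean_err_x": float(res.err_x.mean()),
                             "cat_err_x": float(np.percentile(res.err_x, 99))})
    return pd.DataFrame(rows)
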