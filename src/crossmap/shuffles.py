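"""Surrogate ensembles and corrected per-bin significance for distance tuning.

Two fundamentally different nulls are required simultaneously:

* rigid shuffle — per flight, all spike times are circularly shifted by one
  uniform random offset within the flight, preserving within-flight patterns;
* solo-projection shuffle — spikes of a randomly drawn same-direction solo
  flight are assigned interbat distances through the cross-over flight's
  position-to-distance relation, embodying the position-only null.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .behavior import CrossoverFlight
from .tuning import (
    DISTANCE_MIN_OCC,
    FIELD_DISTANCE_MIN_OCC,
    MIN_CROSS_SPIKES,
    SAMPLE_DT,
    TuningCurve1D,
    distance_edges,
    distance_tuning,
)
from .utils import (
    as_rng,
    bin_centers,
    boxcar_kernel,
    contiguous_runs,
    digitize_clipped,
    smooth_valid_1d,
)

DEFAULT_N_PLACE = 1000
DEFAULT_N_DISTANCE = 10000
ALPHA_BASE = 0.05
N_TOTAL_BINS = 40
N_BINS_IN_WIDTH = 4


def corrected_alpha(alpha: float = ALPHA_BASE, n_total_bins: int = N_TOTAL_BINS,
                    n_bins_in_width: int = N_BINS_IN_WIDTH) -> float:
    """Two-sided per-bin level: (alpha / N_total_bins) * N_bins_in_width."""
    return alpha / n_total_bins * n_bins_in_width


@dataclass
class ShuffleEnsemble:
    """A stack of surrogate distance tunings sharing the data's binning."""

    kind: str                       # 'rigid' | 'solo_projection'
    rates: np.ndarray               # (n, nbins), smoothed
    valid: np.ndarray               # shared validity mask
    edges: np.ndarray
    spike_d: list[np.ndarray] = dfield(default_factory=list, repr=False)
    spike_x: list[np.ndarray] = dfield(default_factory=list, repr=False)
    flight_ids: list[np.ndarray] = dfield(default_factory=list, repr=False)

    @property
    def n(self) -> int:
        return self.rates.shape[0]


def rigid_shuffle_times(spike_times: np.ndarray,
                        windows: list[tuple[float, float]], n: int,
                        rng) -> np.ndarray:
    """(n, n_spikes) circularly shifted spike times, one offset per flight."""
    rng = as_rng(rng)
    spike_times = np.asarray(spike_times, dtype=float)
    out = np.tile(spike_times, (n, 1))
    for (t0, t1) in windows:
        dur = t1 - t0
        if dur <= 0:
            continue
        sel = (spike_times >= t0) & (spike_times <= t1)
        if not sel.any():
            continue
        offs = rng.uniform(0.0, dur, size=n)
        shifted = (spike_times[sel][None, :] - t0 + offs[:, None]) % dur + t0
        out[:, sel] = shifted
    return out


def _stack_tunings(spike_d_per_surrogate: list[np.ndarray],
                   occ: np.ndarray, valid: np.ndarray,
                   edges: np.ndarray) -> np.ndarray:
    """Histogram each surrogate's spike distances and convert to smoothed rates
    against the shared behavioural occupancy."""
    n = len(spike_d_per_surrogate)
    nb = edges.size - 1
    counts = np.zeros((n, nb))
    for i, sd in enumerate(spike_d_per_surrogate):
        idx = digitize_clipped(np.asarray(sd, dtype=float), edges)
        idx = idx[idx >= 0]
        counts[i] = np.bincount(idx, minlength=nb)
    kernel = boxcar_kernel(3)
    sc = smooth_valid_1d(counts, valid, kernel)
    so = smooth_valid_1d(occ, valid, kernel)
    rates = np.full_like(counts, np.nan)
    ok = np.broadcast_to(valid & (so > 0), counts.shape)
    rates[ok] = (sc / np.broadcast_to(so, counts.shape))[ok]
    return rates


def crossover_occupancy(crossovers: list[CrossoverFlight],
                        edges: np.ndarray) -> np.ndarray:
    nb = edges.size - 1
    occ = np.zeros(nb)
    for c in crossovers:
        idx = digitize_clipped(c.d, edges)
        idx = idx[idx >= 0]
        occ += np.bincount(idx, minlength=nb)
    return occ * SAMPLE_DT


def spikes_to_distance(spike_times: np.ndarray,
                       crossovers: list[CrossoverFlight]) -> tuple[np.ndarray, np.ndarray]:
    """Interbat distance of each in-window spike; returns (d, flight_index)."""
    ds, fids = [], []
    for k, c in enumerate(crossovers):
        sel = (spike_times >= c.t[0]) & (spike_times <= c.t[-1])
        if sel.any():
            ds.append(np.interp(spike_times[sel], c.t, c.d))
            fids.append(np.full(sel.sum(), k))
    if not ds:
        return np.array([]), np.array([], dtype=int)
    return np.concatenate(ds), np.concatenate(fids)


def rigid_shuffle(spike_times: np.ndarray, crossovers: list[CrossoverFlight],
                  n: int, rng, variant: str = "full",
                  region: tuple[float, float] | None = None) -> ShuffleEnsemble:
    """Rigid-circular-shift surrogate ensemble of distance tunings."""
    rng = as_rng(rng)
    edges = distance_edges("full" if variant == "full" else "field")
    min_occ = DISTANCE_MIN_OCC if variant == "full" else FIELD_DISTANCE_MIN_OCC
    occ, valid = _region_occupancy(crossovers, edges, min_occ, region)

    windows = [(float(c.t[0]), float(c.t[-1])) for c in crossovers]
    shuffled = rigid_shuffle_times(spike_times, windows, n, rng)
    spike_d, spike_x, flight_ids = [], [], []
    for row in shuffled:
        d, x, fid = _spike_dx_in_region(row, crossovers, region)
        spike_d.append(d)
        spike_x.append(x)
        flight_ids.append(fid)
    rates = _stack_tunings(spike_d, occ, valid, edges)
    return ShuffleEnsemble(kind="rigid", rates=rates, valid=valid, edges=edges,
                           spike_d=spike_d, spike_x=spike_x,
                           flight_ids=flight_ids)


def _region_occupancy(crossovers, edges, min_occ, region):
    nb = edges.size - 1
    occ = np.zeros(nb)
    for c in crossovers:
        d = c.d
        if region is not None:
            sel = (c.x >= region[0]) & (c.x < region[1])
            d = d[sel]
        idx = digitize_clipped(d, edges)
        idx = idx[idx >= 0]
        occ += np.bincount(idx, minlength=nb)
    occ *= SAMPLE_DT
    return occ, occ >= min_occ


def _spike_dx_in_region(spike_times, crossovers, region):
    ds, xs_all, fids = [], [], []
    for k, c in enumerate(crossovers):
        sel = (spike_times >= c.t[0]) & (spike_times <= c.t[-1])
        if not sel.any():
            continue
        ts = spike_times[sel]
        if region is not None:
            xs = np.interp(ts, c.t, c.x)
            ts = ts[(xs >= region[0]) & (xs < region[1])]
            if ts.size == 0:
                continue
        ds.append(np.interp(ts, c.t, c.d))
        xs_all.append(np.interp(ts, c.t, c.x))
        fids.append(np.full(ds[-1].size, k))
    if not ds:
        e = np.array([])
        return e, e.copy(), np.array([], dtype=int)
    return np.concatenate(ds), np.concatenate(xs_all), np.concatenate(fids)


def solo_pools(crossovers: list[CrossoverFlight], solo_flights: list[dict],
               coverage: float = 0.9) -> list[list[int]]:
    """For each cross-over flight, indices of same-direction solo flights whose
    position span covers >= ``coverage`` of the cross-over's span."""
    pools = []
    for c in crossovers:
        lo, hi = float(np.min(c.x)), float(np.max(c.x))
        span = hi - lo
        pool = []
        for j, s in enumerate(solo_flights):
            if s["direction"] != c.direction:
                continue
            slo, shi = float(np.min(s["x"])), float(np.max(s["x"]))
            overlap = max(0.0, min(hi, shi) - max(lo, slo))
            if span <= 0 or overlap / span >= coverage:
                pool.append(j)
        pools.append(pool)
    return pools


def solo_projection_shuffle(spike_times: np.ndarray,
                            crossovers: list[CrossoverFlight],
                            solo_flights: list[dict], n: int, rng,
                            variant: str = "full",
                            region: tuple[float, float] | None = None) -> ShuffleEnsemble:
    """Project solo spikes onto cross-over behaviour, n independent times.

    Cross-over flights without any covering solo flight are dropped from the
    ensemble (warning recorded through the returned flight lists).
    """
    rng = as_rng(rng)
    edges = distance_edges("full" if variant == "full" else "field")
    min_occ = DISTANCE_MIN_OCC if variant == "full" else FIELD_DISTANCE_MIN_OCC
    occ, valid = _region_occupancy(crossovers, edges, min_occ, region)
    pools = solo_pools(crossovers, solo_flights)

    # per-solo-flight spike positions, precomputed once
    solo_spike_x = []
    for s in solo_flights:
        sel = (spike_times >= s["t"][0]) & (spike_times <= s["t"][-1])
        solo_spike_x.append(np.interp(spike_times[sel], s["t"], s["x"]))

    # per-cross-over monotone (x, d) relation for interpolation
    relations = []
    for c in crossovers:
        order = np.argsort(c.x)
        relations.append((c.x[order], c.d[order]))

    spike_d, spike_x, flight_ids = [], [], []
    for _ in range(n):
        ds, xs_all, fids = [], [], []
        for k, (c, pool) in enumerate(zip(crossovers, pools)):
            if not pool:
                continue
            j = pool[rng.integers(len(pool))]
            xs = solo_spike_x[j]
            xk, dk = relations[k]
            sel = (xs >= xk[0]) & (xs <= xk[-1])
            if region is not None:
                sel &= (xs >= region[0]) & (xs < region[1])
            if not sel.any():
                continue
            ds.append(np.interp(xs[sel], xk, dk))
            xs_all.append(xs[sel])
            fids.append(np.full(sel.sum(), k))
        spike_d.append(np.concatenate(ds) if ds else np.array([]))
        spike_x.append(np.concatenate(xs_all) if xs_all else np.array([]))
        flight_ids.append(np.concatenate(fids) if fids else np.array([], dtype=int))
    rates = _stack_tunings(spike_d, occ, valid, edges)
    return ShuffleEnsemble(kind="solo_projection", rates=rates, valid=valid,
                           edges=edges, spike_d=spike_d, spike_x=spike_x,
                           flight_ids=flight_ids)


@dataclass
class SignificanceResult:
    flags: np.ndarray              # per-bin: +1 enhanced, -1 suppressed, 0
    edges: np.ndarray
    alpha_corrected: float
    runs: list[tuple[int, int, int]] = dfield(default_factory=list)  # (start, stop, polarity)

    @property
    def any_significant(self) -> bool:
        return bool(np.any(self.flags != 0))

    @property
    def onset(self) -> float | None:
        idx = np.flatnonzero(self.flags != 0)
        if idx.size == 0:
            return None
        centers = bin_centers(self.edges)
        return float(centers[idx[0]])


def _frac_beyond(data: np.ndarray, ens: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin fractions of surrogates >= data and <= data (ties count against
    significance)."""
    with np.errstate(invalid="ignore"):
        ge = np.nanmean(ens >= data[None, :], axis=0)
        le = np.nanmean(ens <= data[None, :], axis=0)
    return ge, le


def significant_bins(data_rate: np.ndarray, ens_a: ShuffleEnsemble,
                     ens_b: ShuffleEnsemble | None = None,
                     mode: str = "full_1d",
                     data_flight_ids: np.ndarray | None = None,
                     data_spike_d: np.ndarray | None = None,
                     min_ensemble: int = 100) -> SignificanceResult:
    """Corrected per-bin significance against one or two surrogate ensembles.

    ``full_1d`` requires the 99.5%/0.5% criterion in both ensembles;
    ``field_level`` requires 99.5%/0.5% in one and 95%/5% in the other, plus
    >= 2 contributing flights per significant run (pass ``data_flight_ids`` /
    ``data_spike_d`` for that check). Edge bins and singleton bins are always
    deflagged.
    """
    for ens in (ens_a, ens_b):
        if ens is not None and ens.n < min_ensemble:
            raise ValueError(f"ensemble too small ({ens.n} < {min_ensemble})")
    alpha_c = corrected_alpha()
    half = alpha_c / 2.0

    ge_a, le_a = _frac_beyond(data_rate, ens_a.rates)
    if ens_b is not None:
        ge_b, le_b = _frac_beyond(data_rate, ens_b.rates)
    valid = ens_a.valid & np.isfinite(data_rate)

    if mode == "full_1d":
        if ens_b is None:
            raise ValueError("full_1d mode needs both ensembles")
        enh = (ge_a < half) & (ge_b < half)
        sup = (le_a < half) & (le_b < half)
    elif mode == "field_level":
        if ens_b is None:
            raise ValueError("field_level mode needs both ensembles")
        enh = ((ge_a < half) & (ge_b < ALPHA_BASE)) | ((ge_b < half) & (ge_a < ALPHA_BASE))
        sup = ((le_a < half) & (le_b < ALPHA_BASE)) | ((le_b < half) & (le_a < ALPHA_BASE))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    enh &= valid
    sup &= valid

    flags = np.zeros(data_rate.size, dtype=int)
    flags[enh] = 1
    flags[sup] = -1
    # edge deflagging
    flags[0] = 0
    flags[-1] = 0
    # adjacency: runs of identical polarity must span >= 2 bins
    runs = []
    for pol in (1, -1):
        for i0, i1 in contiguous_runs(flags == pol):
            if i1 - i0 < 2:
                flags[i0:i1] = 0
                continue
            if mode == "field_level" and data_flight_ids is not None \
                    and data_spike_d is not None:
                idx = digitize_clipped(data_spike_d, ens_a.edges)
                inside = (idx >= i0) & (idx < i1)
                if np.unique(data_flight_ids[inside]).size < 2:
                    flags[i0:i1] = 0
                    continue
            runs.append((i0, i1, pol))
    return SignificanceResult(flags=flags, edges=ens_a.edges,
                              alpha_corrected=alpha_c, runs=runs)


@dataclass
class DistanceCellResult:
    is_distance_cell: bool
    significance: SignificanceResult | None
    n_cross_spikes: int
    stability_r: float
    tuning: TuningCurve1D | None = None
    reason: str = ""


def odd_even_stability(spike_times: np.ndarray,
                       crossovers: list[CrossoverFlight]) -> float:
    """Pearson r between distance tunings of odd and even cross-over flights."""
    halves = []
    for par in (0, 1):
        cs = [c for i, c in enumerate(crossovers) if i % 2 == par]
        d, _ = spikes_to_distance(spike_times, cs)
        behav = np.concatenate([c.d for c in cs]) if cs else np.array([])
        halves.append(distance_tuning(d, behav))
    a, b = halves
    ok = a.valid & b.valid & np.isfinite(a.rate) & np.isfinite(b.rate)
    if ok.sum() < 3 or np.nanstd(a.rate[ok]) == 0 or np.nanstd(b.rate[ok]) == 0:
        return np.nan
    return float(np.corrcoef(a.rate[ok], b.rate[ok])[0, 1])


def classify_distance_cell(spike_times: np.ndarray,
                           crossovers: list[CrossoverFlight],
                           solo_flights: list[dict],
                           n_shuffle: int = DEFAULT_N_DISTANCE,
                           rng=None,
                           min_crossovers: int = 10,
                           min_ensemble: int = 100) -> DistanceCellResult:
    """Full 1D distance-cell decision: both shuffles, corrected bins,
    >= 30 cross-over spikes and odd/even stability r >= 0.3."""
    rng = as_rng(rng)
    if len(crossovers) < min_crossovers:
        return DistanceCellResult(False, None, 0, np.nan,
                                  reason="lt_10_crossovers")
    d, fids = spikes_to_distance(spike_times, crossovers)
    behav = np.concatenate([c.d for c in crossovers])
    curve = distance_tuning(d, behav)
    n_spk = d.size

    ens_r = rigid_shuffle(spike_times, crossovers, n_shuffle, rng)
    ens_s = solo_projection_shuffle(spike_times, crossovers, solo_flights,
                                    n_shuffle, rng)
    sig = significant_bins(curve.rate, ens_r, ens_s, mode="full_1d",
                           min_ensemble=min_ensemble)
    r = odd_even_stability(spike_times, crossovers)

    reasons = []
    if not sig.any_significant:
        reasons.append("no_significant_bins")
    if n_spk < MIN_CROSS_SPIKES:
        reasons.append("lt_30_spikes")
    if not (np.isfinite(r) and r >= 0.3):
        reasons.append("unstable")
    return DistanceCellResult(is_distance_cell=not reasons, significance=sig,
                              n_cross_spikes=int(n_spk), stability_r=r,
                              tuning=curve, reason=",".join(reasons))


@dataclass
class SwitchTimes:
    rise_time: float
    fall_time: float
    polarity: str                 # 'enhancement' | 'suppression'


def switch_times(data_rate: np.ndarray, shuffle_median: np.ndarray,
                 flags: np.ndarray, time_centers: np.ndarray,
                 upsample: int = 10) -> SwitchTimes | None:
    """Rise/fall times of a single-polarity modulation on a time axis.

    Both curves are x10 linearly upsampled; rise = time from crossing the
    shuffle median to the first significant bin (enhancement), fall is the
    mirror on the far side. Returns None when the tuning is mixed-polarity or
    never crosses the median on both sides.
    """
    pols = set(np.unique(flags[flags != 0]).tolist())
    if pols not in ({1}, {-1}):
        return None
    pol = pols.pop()
    ok = np.isfinite(data_rate) & np.isfinite(shuffle_median)
    t = time_centers[ok]
    data = data_rate[ok]
    med = shuffle_median[ok]
    fl = flags[ok]
    tf = np.linspace(t[0], t[-1], t.size * upsample)
    df = np.interp(tf, t, data)
    mf = np.interp(tf, t, med)
    above = (df > mf) if pol == 1 else (df < mf)
    sig_idx = np.flatnonzero(fl != 0)
    t_first, t_last = t[sig_idx[0]], t[sig_idx[-1]]
    # crossing before the first significant bin
    pre = np.flatnonzero(~above & (tf < t_first))
    post = np.flatnonzero(~above & (tf > t_last))
    if pre.size == 0 or post.size == 0:
        return None
    t_cross_pre = tf[pre[-1]]
    t_cross_post = tf[post[0]]
    rise = float(t_first - t_cross_pre)
    fall = float(t_cross_post - t_last)
    if pol == -1:
        rise, fall = fall, rise
    return SwitchTimes(rise_time=rise, fall_time=fall,
                       polarity="enhancement" if pol == 1 else "suppression")
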