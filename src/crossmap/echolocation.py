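"""Click detection, click-rate profiles, attention split and neural controls.

Echolocation click rate rises steeply in the last ~20 m before a cross-over
and serves as a moment-to-moment attention index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .behavior import CrossoverFlight
from .shuffles import corrected_alpha
from .tuning import MIN_CROSS_SPIKES, distance_edges, distance_tuning
from .utils import (
    as_rng,
    bin_centers,
    contiguous_runs,
    digitize_clipped,
    gaussian_kernel_1d,
    smooth_valid_1d,
)

SPEED_OF_SOUND = 343.0  # m/s; not stated by the hardware, fixed here


@dataclass(frozen=True)
class ClickDetectorConfig:
    sample_rate: float = 100_000.0
    highpass_hz: float = 10_000.0
    snr_threshold: float = 50.0          # in MAD units
    click_duration_us: tuple[float, float] = (30.0, 2500.0)
    max_rise_us: float = 500.0
    min_ici_ms: float = 10.0
    band_hi: tuple[float, float] = (18_000.0, 40_000.0)
    band_lo: tuple[float, float] = (5_000.0, 12_000.0)
    min_band_ratio_db: float = 10.0
    other_snr_range: tuple[float, float] = (50.0, 200.0)
    toa_tolerance_ms: float = 3.0
    speed_of_sound: float = SPEED_OF_SOUND
    merge_gap_us: float = 300.0
    boundary_snr: float = 10.0    # envelope level defining click extent


@dataclass
class ClickTrain:
    times: np.ndarray
    snr: np.ndarray
    source: np.ndarray            # 'self' | 'other' | 'rejected'

    def accepted(self) -> np.ndarray:
        return self.times[self.source == "self"]


def _band_energy(seg: np.ndarray, sr: float, band: tuple[float, float]) -> float:
    freqs = np.fft.rfftfreq(seg.size, 1.0 / sr)
    spec = np.abs(np.fft.rfft(seg)) ** 2
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(spec[sel].sum())


def detect_clicks(audio: np.ndarray, cfg: ClickDetectorConfig,
                  other_click_times: np.ndarray | None = None,
                  d_of_t: tuple[np.ndarray, np.ndarray] | None = None) -> ClickTrain:
    """Threshold-based click detection on MAD-normalised, high-passed audio.

    When the partner's click times and the interbat-distance series ``(t, d)``
    are supplied, low-SNR candidates near the expected time of arrival
    (|d| / speed of sound, +-3 ms) are labelled ``other`` and removed from the
    accepted train.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.size == 0 or np.ptp(audio) == 0:
        e = np.array([])
        return ClickTrain(e, e, np.array([], dtype=object))
    sos = signal.butter(4, cfg.highpass_hz, btype="high", fs=cfg.sample_rate,
                        output="sos")
    filt = signal.sosfiltfilt(sos, audio)
    mad = np.mean(np.abs(filt - np.mean(filt)))
    if mad == 0:
        e = np.array([])
        return ClickTrain(e, e, np.array([], dtype=object))
    snr = np.abs(filt) / mad
    # duration and rise time are measured on the envelope at a lower boundary
    # level: at threshold SNR only the very peak exceeds 50 MADs
    envelope = np.abs(signal.hilbert(filt)) / mad
    above_boundary = envelope >= cfg.boundary_snr

    above = snr >= cfg.snr_threshold
    if not above.any():
        e = np.array([])
        return ClickTrain(e, e, np.array([], dtype=object))
    # merge supra-threshold samples separated by less than merge_gap
    gap = int(cfg.merge_gap_us * 1e-6 * cfg.sample_rate)
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > gap)
    groups = np.split(idx, breaks + 1)

    times, snrs, sources = [], [], []
    last_accept = -np.inf
    for g in groups:
        peak = g[0] + int(np.argmax(snr[g[0]:g[-1] + 1]))
        # expand to the contiguous envelope extent around the peak
        i0 = peak
        while i0 > 0 and above_boundary[i0 - 1]:
            i0 -= 1
        i1 = peak
        while i1 < above_boundary.size - 1 and above_boundary[i1 + 1]:
            i1 += 1
        duration_us = (i1 - i0 + 1) / cfg.sample_rate * 1e6
        env_peak = i0 + int(np.argmax(envelope[i0:i1 + 1]))
        rise_us = (env_peak - i0) / cfg.sample_rate * 1e6
        t = peak / cfg.sample_rate
        s = float(snr[peak])
        ok = (cfg.click_duration_us[0] <= duration_us <= cfg.click_duration_us[1]
              and rise_us <= cfg.max_rise_us)
        if ok:
            half = int(0.001 * cfg.sample_rate)
            seg = filt[max(0, peak - half):peak + half]
            e_hi = _band_energy(seg, cfg.sample_rate, cfg.band_hi)
            e_lo = _band_energy(seg, cfg.sample_rate, cfg.band_lo)
            ratio_db = 10.0 * np.log10(e_hi / e_lo) if e_lo > 0 else np.inf
            ok = ratio_db >= cfg.min_band_ratio_db
        if ok and (t - last_accept) * 1e3 < cfg.min_ici_ms:
            ok = False
        label = "self" if ok else "rejected"
        if ok and other_click_times is not None and d_of_t is not None \
                and cfg.other_snr_range[0] <= s <= cfg.other_snr_range[1]:
            td, dd = d_of_t
            delays = np.abs(np.interp(other_click_times, td, dd)) / cfg.speed_of_sound
            expected = other_click_times + delays
            if np.any(np.abs(expected - t) <= cfg.toa_tolerance_ms * 1e-3):
                label = "other"
        if label == "self":
            last_accept = t
        times.append(t)
        snrs.append(s)
        sources.append(label)
    return ClickTrain(np.asarray(times), np.asarray(snrs),
                      np.asarray(sources, dtype=object))


def click_distance_profile(click_times: np.ndarray,
                           crossovers: list[CrossoverFlight]):
    """1D click-rate tuning over interbat distance (shared binning engine)."""
    ds, behav = [], []
    for c in crossovers:
        sel = (click_times >= c.t[0]) & (click_times <= c.t[-1])
        ds.append(np.interp(click_times[sel], c.t, c.d))
        behav.append(c.d)
    d = np.concatenate(ds) if ds else np.array([])
    b = np.concatenate(behav) if behav else np.array([])
    return distance_tuning(d, b)


def per_flight_click_rate(click_times: np.ndarray, c: CrossoverFlight,
                          dt: float = 0.01) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed per-flight click-rate curve over distance (2 m bins,
    Gaussian sigma = 1.5 bins); returns (centers, rate, valid)."""
    edges = distance_edges("full")
    nb = edges.size - 1
    sel = (click_times >= c.t[0]) & (click_times <= c.t[-1])
    d_clicks = np.interp(click_times[sel], c.t, c.d)
    occ = np.bincount(digitize_clipped(c.d, edges) + 1, minlength=nb + 1)[1:] * dt
    cnt = np.bincount(digitize_clipped(d_clicks, edges) + 1,
                      minlength=nb + 1)[1:].astype(float)
    valid = occ > 0
    kernel = gaussian_kernel_1d(1.5)
    sc = smooth_valid_1d(cnt, valid, kernel)
    so = smooth_valid_1d(occ, valid, kernel)
    rate = np.full(nb, np.nan)
    ok = valid & (so > 0)
    rate[ok] = sc[ok] / so[ok]
    return bin_centers(edges), rate, valid


@dataclass
class AttentionSplit:
    high: np.ndarray              # flight indices (into the crossover list)
    low: np.ndarray
    rates: np.ndarray             # mean click rate in the split window per flight
    valid_flights: np.ndarray
    refused: bool = False
    refuse_reason: str = ""

    @property
    def n_valid(self) -> int:
        return int(self.valid_flights.sum())


SPLIT_WINDOW = (-15.0, 0.0)
CONTINUITY_WINDOW = (-25.0, 5.0)
PEAK_RATE_MIN_HZ = 10.0
MIN_FOLD_CHANGE = 2.0
MIN_VALID_FLIGHTS = 20
PRECEDING_MIN_D = -15.0       # the "preceding minimum" is taken at d < -15 m


def attention_split(crossovers: list[CrossoverFlight],
                    click_times: np.ndarray) -> AttentionSplit:
    """Median bisection of valid cross-over flights by click rate in -15..0 m.

    Flights are invalid if the distance series does not continuously cover
    -25..5 m, the peak click rate is <= 10 Hz, or the modulation relative to
    the flight's preceding minimum (d < -15 m) is <= 2-fold. Ties are broken
    deterministically by (rate, flight index).
    """
    n = len(crossovers)
    rates = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, c in enumerate(crossovers):
        if not (c.d.min() <= CONTINUITY_WINDOW[0] and c.d.max() >= CONTINUITY_WINDOW[1]):
            continue
        centers, rate, _ = per_flight_click_rate(click_times, c)
        finite = np.isfinite(rate)
        if not finite.any() or np.nanmax(rate) <= PEAK_RATE_MIN_HZ:
            continue
        pre = finite & (centers < PRECEDING_MIN_D)
        if not pre.any():
            continue
        pre_min = np.nanmin(rate[pre])
        if pre_min > 0 and np.nanmax(rate) / pre_min <= MIN_FOLD_CHANGE:
            continue
        win = finite & (centers >= SPLIT_WINDOW[0]) & (centers < SPLIT_WINDOW[1])
        if not win.any():
            continue
        rates[i] = np.nanmean(rate[win])
        valid[i] = True

    vi = np.flatnonzero(valid)
    if vi.size < MIN_VALID_FLIGHTS:
        return AttentionSplit(np.array([], dtype=int), np.array([], dtype=int),
                              rates, valid, refused=True,
                              refuse_reason=f"{vi.size} valid flights < {MIN_VALID_FLIGHTS}")
    order = vi[np.lexsort((vi, rates[vi]))]
    half = order.size // 2
    low, high = order[:half], order[half:]
    if order.size % 2 == 1:
        # odd count: the middle flight goes to the high group (sizes differ by 1)
        pass
    return AttentionSplit(high=np.sort(high), low=np.sort(low), rates=rates,
                          valid_flights=valid)


@dataclass
class AttentionModulationResult:
    peak_diff: float
    mean_diff: float
    peak_pct: float
    mean_pct: float
    significant: bool
    excluded: bool = False
    reason: str = ""


def _per_flight_histograms(spike_times, crossovers, edges, dt=0.01):
    """Per-flight spike-count and occupancy histograms over distance bins."""
    nb = edges.size - 1
    counts = np.zeros((len(crossovers), nb))
    occ = np.zeros((len(crossovers), nb))
    for i, c in enumerate(crossovers):
        sel = (spike_times >= c.t[0]) & (spike_times <= c.t[-1])
        d_spk = np.interp(spike_times[sel], c.t, c.d)
        counts[i] = np.bincount(digitize_clipped(d_spk, edges) + 1,
                                minlength=nb + 1)[1:]
        occ[i] = np.bincount(digitize_clipped(c.d, edges) + 1,
                             minlength=nb + 1)[1:] * dt
    return counts, occ


def _group_stats(counts, occ, rows, win_sel, kernel, min_occ=0.4):
    """Peak and mean smoothed rate inside the analysis window for one group."""
    c = counts[rows].sum(axis=0)
    o = occ[rows].sum(axis=0)
    valid = o >= min_occ
    sc = smooth_valid_1d(c, valid, kernel)
    so = smooth_valid_1d(o, valid, kernel)
    rate = np.full(c.size, np.nan)
    ok = valid & (so > 0)
    rate[ok] = sc[ok] / so[ok]
    sel = win_sel & np.isfinite(rate)
    if not sel.any():
        return np.nan, np.nan, int(c.sum())
    return float(np.nanmax(rate[sel])), float(np.nanmean(rate[sel])), int(c.sum())


def attention_modulation_test(spike_times: np.ndarray,
                              crossovers: list[CrossoverFlight],
                              split: AttentionSplit,
                              n_shuffle: int = 10_000, rng=None) -> AttentionModulationResult:
    """High-minus-low tuning differences vs a random-bisection null.

    Quantities are the peak-rate and mean-rate differences within +-10 m of
    the all-flight tuning peak; the cell is significant if either exceeds the
    95th percentile of its null.
    """
    rng = as_rng(rng)
    if split.refused:
        return AttentionModulationResult(np.nan, np.nan, np.nan, np.nan, False,
                                         excluded=True, reason=split.refuse_reason)
    all_idx = np.concatenate([split.high, split.low])
    ds, behav = [], []
    for i in all_idx:
        c = crossovers[i]
        sel = (spike_times >= c.t[0]) & (spike_times <= c.t[-1])
        ds.append(np.interp(spike_times[sel], c.t, c.d))
        behav.append(c.d)
    full = distance_tuning(np.concatenate(ds), np.concatenate(behav))
    if not np.isfinite(full.rate).any():
        return AttentionModulationResult(np.nan, np.nan, np.nan, np.nan, False,
                                         excluded=True, reason="no_tuning")
    peak_d = float(full.centers[np.nanargmax(full.rate)])
    window = (peak_d - 10.0, peak_d + 10.0)
    win_sel = (full.centers >= window[0]) & (full.centers <= window[1])
    kernel = np.full(3, 1.0 / 3.0)

    counts, occ = _per_flight_histograms(spike_times, crossovers, full.edges)
    hp, hm, n_hi = _group_stats(counts, occ, split.high, win_sel, kernel)
    lp, lm, n_lo = _group_stats(counts, occ, split.low, win_sel, kernel)
    if max(n_hi, n_lo) < MIN_CROSS_SPIKES:
        return AttentionModulationResult(np.nan, np.nan, np.nan, np.nan, False,
                                         excluded=True, reason="lt_30_spikes_per_group")
    peak_diff = hp - lp
    mean_diff = hm - lm

    null_peak = np.empty(n_shuffle)
    null_mean = np.empty(n_shuffle)
    n_high = split.high.size
    for s in range(n_shuffle):
        perm = rng.permutation(all_idx)
        hp_s, hm_s, _ = _group_stats(counts, occ, perm[:n_high], win_sel, kernel)
        lp_s, lm_s, _ = _group_stats(counts, occ, perm[n_high:], win_sel, kernel)
        null_peak[s] = hp_s - lp_s
        null_mean[s] = hm_s - lm_s
    peak_pct = float(np.nanmean(null_peak < peak_diff))
    mean_pct = float(np.nanmean(null_mean < mean_diff))
    return AttentionModulationResult(peak_diff, mean_diff, peak_pct, mean_pct,
                                     significant=bool(peak_pct > 0.95 or mean_pct > 0.95))


def contrast_index(cr1: float, cr2: float) -> float:
    """(CR1 - CR2) / (CR1 + CR2); antisymmetric under field swap."""
    if cr1 + cr2 == 0:
        return 0.0
    return (cr1 - cr2) / (cr1 + cr2)


@dataclass
class ClickTriggeredResult:
    centers: np.ndarray           # s, relative to click
    psth: np.ndarray              # mean spikes per bin per click
    flags: np.ndarray             # +1 / -1 / 0 per bin
    low_power: bool


PSTH_WINDOW = 0.2                # s each side
PSTH_BIN = 0.01                  # s
MIN_SOLO_CLICKS = 100


def click_triggered_control(spike_times: np.ndarray, solo_click_times: np.ndarray,
                            n_shuffle: int = 10_000, rng=None) -> ClickTriggeredResult:
    """Peri-click spike histogram vs rigid circular shuffles within +-200 ms.

    Per-bin significance at the corrected 99.5%/0.5% level (4-bin assumed
    response width) with a >= 2 consecutive-bin requirement.
    """
    rng = as_rng(rng)
    edges = np.arange(-PSTH_WINDOW, PSTH_WINDOW + PSTH_BIN / 2, PSTH_BIN)
    nb = edges.size - 1
    n_clicks = solo_click_times.size
    low_power = n_clicks < MIN_SOLO_CLICKS
    rel = []
    for t0 in solo_click_times:
        sel = (spike_times >= t0 - PSTH_WINDOW) & (spike_times < t0 + PSTH_WINDOW)
        rel.append(spike_times[sel] - t0)
    rel_all = np.concatenate(rel) if rel else np.array([])
    counts = np.bincount(digitize_clipped(rel_all, edges) + 1,
                         minlength=nb + 1)[1:].astype(float)
    psth = counts / max(n_clicks, 1)

    # null: circular shift of the relative spike times within the window
    null = np.zeros((n_shuffle, nb))
    span = 2 * PSTH_WINDOW
    for i, r in enumerate(rel):
        if r.size == 0:
            continue
        offs = rng.uniform(0.0, span, size=n_shuffle)
        shifted = (r[None, :] + PSTH_WINDOW + offs[:, None]) % span - PSTH_WINDOW
        idx = np.clip(((shifted + PSTH_WINDOW) / PSTH_BIN).astype(int), 0, nb - 1)
        flat = (np.arange(n_shuffle)[:, None] * nb + idx).ravel()
        null += np.bincount(flat, minlength=n_shuffle * nb).reshape(n_shuffle, nb)
    null /= max(n_clicks, 1)

    alpha_c = corrected_alpha(n_total_bins=nb, n_bins_in_width=4)
    half = alpha_c / 2.0
    ge = (null >= psth[None, :]).mean(axis=0)
    le = (null <= psth[None, :]).mean(axis=0)
    flags = np.zeros(nb, dtype=int)
    flags[ge < half] = 1
    flags[le < half] = -1
    for pol in (1, -1):
        for i0, i1 in contiguous_runs(flags == pol):
            if i1 - i0 < 2:
                flags[i0:i1] = 0
    return ClickTriggeredResult(centers=bin_centers(edges), psth=psth,
                                flags=flags, low_power=low_power)
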