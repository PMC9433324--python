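"""Occupancy-normalised tuning curves, place-field detection and controls.

Binning conventions (half-open bins, edges anchored at round numbers):

=============  ==========  ====================  ============
variable       bin width   smoothing             min occupancy
=============  ==========  ====================  ============
position       0.5 m       Gaussian sigma=3 bins  0.8 s
distance       2 m         boxcar 3 bins          0.4 s
field distance 80/30 m     boxcar 3 bins          0.1 s
movement       0.2 m/s     boxcar 3 bins          0.4 s
(lateral speed 0.1 m/s)
=============  ==========  ====================  ============
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .utils import (
    bin_centers,
    bin_edges,
    boxcar_kernel,
    digitize_clipped,
    gaussian_kernel_1d,
    smooth_valid_1d,
)

POSITION_BIN = 0.5
POSITION_SIGMA_BINS = 3.0
POSITION_MIN_OCC = 0.8
DISTANCE_BIN = 2.0
DISTANCE_MIN_OCC = 0.4
DISTANCE_RANGE = 40.0
FIELD_DISTANCE_NBINS = 30
FIELD_DISTANCE_MIN_OCC = 0.1
SAMPLE_DT = 0.01  # s, occupancy increment per 100 Hz behavioural sample

PLACE_PEAK_MIN = 0.5        # Hz
FIELD_BOUND_FRAC = 0.2      # field extends while rate >= 20% of peak
DIP_FRAC = 0.5              # shallow-dip absorption threshold
SI_MIN = 0.25               # bits/spike
MIN_SOLO_SPIKES = 50
MIN_CROSS_SPIKES = 30


@dataclass
class TuningCurve1D:
    """Binned, occupancy-normalised, smoothed firing-rate curve."""

    edges: np.ndarray
    rate: np.ndarray
    occupancy: np.ndarray          # seconds, pre-smoothing
    spike_counts: np.ndarray       # raw counts, pre-smoothing
    valid: np.ndarray
    variable: str = "position"
    analyzable: bool = True
    not_analyzable_reason: str = ""

    @property
    def centers(self) -> np.ndarray:
        return bin_centers(self.edges)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_counts.sum())


def _rate_from_counts(counts: np.ndarray, occ: np.ndarray, valid: np.ndarray,
                      kernel: np.ndarray) -> np.ndarray:
    """Smooth counts and occupancy separately over valid bins, then divide."""
    sc = smooth_valid_1d(counts, valid, kernel)
    so = smooth_valid_1d(occ, valid, kernel)
    rate = np.full(counts.shape, np.nan)
    ok = np.broadcast_to(valid, counts.shape) & (so > 0)
    rate[ok] = sc[ok] / so[ok]
    return rate


def compute_tuning(spike_values: np.ndarray, behav_values: np.ndarray,
                   edges: np.ndarray, min_occ: float, kernel: np.ndarray,
                   dt: float = SAMPLE_DT, variable: str = "") -> TuningCurve1D:
    """Generic 1D tuning: histogram spikes and behaviour, smooth, divide."""
    nb = edges.size - 1
    occ = np.bincount(
        digitize_clipped(np.asarray(behav_values, dtype=float), edges) + 1,
        minlength=nb + 1)[1:] * dt
    counts = np.bincount(
        digitize_clipped(np.asarray(spike_values, dtype=float), edges) + 1,
        minlength=nb + 1)[1:].astype(float)
    valid = occ >= min_occ
    rate = _rate_from_counts(counts, occ, valid, kernel)
    return TuningCurve1D(edges=edges, rate=rate, occupancy=occ,
                         spike_counts=counts, valid=valid, variable=variable)


def position_tuning(spike_positions: np.ndarray, behav_positions: np.ndarray,
                    track_lo: float = 0.0, track_hi: float = 135.0,
                    dt: float = SAMPLE_DT) -> TuningCurve1D:
    """0.5 m position tuning (Gaussian sigma = 3 bins, 0.8 s occupancy floor).

    ``behav_positions`` may equally be the *other* bat's positions sampled at
    this bat's spike/behaviour times (other-bat reference frame).
    """
    edges = bin_edges(track_lo, track_hi, POSITION_BIN)
    return compute_tuning(spike_positions, behav_positions, edges,
                          POSITION_MIN_OCC, gaussian_kernel_1d(POSITION_SIGMA_BINS),
                          dt=dt, variable="position")


def distance_edges(variant: str = "full") -> np.ndarray:
    if variant == "full":
        return bin_edges(-DISTANCE_RANGE, DISTANCE_RANGE, DISTANCE_BIN)
    return np.linspace(-DISTANCE_RANGE, DISTANCE_RANGE, FIELD_DISTANCE_NBINS + 1)


def distance_tuning(spike_d: np.ndarray, behav_d: np.ndarray,
                    variant: str = "full", dt: float = SAMPLE_DT) -> TuningCurve1D:
    """1D interbat-distance tuning (2 m bins full; 30 coarser bins per region).

    Region variants (within_field / interfield) are marked not analyzable
    unless they hold >= 30 spikes and >= 80% valid bins.
    """
    edges = distance_edges("full" if variant == "full" else "field")
    min_occ = DISTANCE_MIN_OCC if variant == "full" else FIELD_DISTANCE_MIN_OCC
    curve = compute_tuning(spike_d, behav_d, edges, min_occ, boxcar_kernel(3),
                           dt=dt, variable=f"distance_{variant}")
    if variant != "full":
        reasons = []
        if curve.n_spikes < MIN_CROSS_SPIKES:
            reasons.append("lt_30_spikes")
        if curve.valid.mean() < 0.8:
            reasons.append("lt_80pct_valid_bins")
        curve.analyzable = not reasons
        curve.not_analyzable_reason = ",".join(reasons)
    return curve


@dataclass
class SpatialInfo:
    si: float
    mean_rate: float

    @property
    def bits_per_spike(self) -> float:
        return self.si


def spatial_information(rate: np.ndarray, occupancy: np.ndarray,
                        valid: np.ndarray | None = None) -> float:
    """SI (bits/spike) = sum_i p_i (r_i / rbar) log2(r_i / rbar).

    p_i is occupancy renormalised over valid bins; 0 log 0 := 0. Raises if the
    mean rate is zero (undefined).
    """
    rate = np.asarray(rate, dtype=float)
    occupancy = np.asarray(occupancy, dtype=float)
    if valid is None:
        valid = np.isfinite(rate) & (occupancy > 0)
    r = rate[valid]
    p = occupancy[valid]
    if p.sum() <= 0:
        raise ValueError("no valid occupancy")
    p = p / p.sum()
    rbar = float(np.sum(p * r))
    if rbar <= 0:
        raise ValueError("mean rate is zero; SI undefined")
    ratio = r / rbar
    terms = np.where(ratio > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


@dataclass
class PlaceField:
    peak_pos: float
    peak_rate: float
    lo: float
    hi: float
    i_lo: int
    i_hi: int                      # half-open bin indices
    n_laps_with_spikes: int = 0
    local_si_percentile: float = np.nan
    significant: bool = False

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass
class PlaceCellResult:
    fields: list[PlaceField]
    interfields: list[tuple[float, float]]
    is_place_cell: bool
    si: float
    si_percentile: float
    n_spikes: int


def _local_peaks(rate: np.ndarray, valid: np.ndarray) -> list[int]:
    idx = []
    r = np.where(valid & np.isfinite(rate), rate, -np.inf)
    for i in range(r.size):
        left = r[i - 1] if i > 0 else -np.inf
        right = r[i + 1] if i < r.size - 1 else -np.inf
        if r[i] > PLACE_PEAK_MIN and r[i] >= left and r[i] > right:
            idx.append(i)
    return idx


def _absorb_shallow_dips(rate: np.ndarray, peaks: list[int]) -> list[int]:
    """Drop the lower of two adjacent peaks when the dip between them stays
    above 50% of the larger peak's rate."""
    peaks = sorted(peaks)
    changed = True
    while changed and len(peaks) > 1:
        changed = False
        for a, b in zip(peaks[:-1], peaks[1:]):
            dip = np.nanmin(rate[a:b + 1])
            larger = max(rate[a], rate[b])
            if dip > DIP_FRAC * larger:
                peaks.remove(a if rate[a] < rate[b] else b)
                changed = True
                break
    return peaks


def _field_bounds(rate: np.ndarray, valid: np.ndarray, peak: int) -> tuple[int, int]:
    thr = FIELD_BOUND_FRAC * rate[peak]
    lo = peak
    while lo > 0 and valid[lo - 1] and np.isfinite(rate[lo - 1]) and rate[lo - 1] >= thr:
        lo -= 1
    hi = peak
    while (hi < rate.size - 1 and valid[hi + 1] and np.isfinite(rate[hi + 1])
           and rate[hi + 1] >= thr):
        hi += 1
    return lo, hi + 1


def detect_place_fields(curve: TuningCurve1D,
                        lap_spike_positions: list[np.ndarray],
                        shuffle_curves: np.ndarray,
                        lap_behav_positions: list[np.ndarray] | None = None,
                        shuffle_spike_positions: list[np.ndarray] | None = None,
                        min_shuffles: int = 100) -> PlaceCellResult:
    """Five-step field detection plus place-cell classification.

    ``shuffle_curves`` is an (n, nbins) stack of rigid-shuffle position
    tunings; ``shuffle_spike_positions`` (one position array per surrogate) is
    needed for the local-SI field-significance step — fields are accepted
    without that step if it is not supplied.
    """
    n_shuf = shuffle_curves.shape[0]
    if n_shuf < min_shuffles:
        raise ValueError(f"need >= {min_shuffles} shuffles, got {n_shuf}")
    rate, valid, occ = curve.rate, curve.valid, curve.occupancy
    n_spikes = curve.n_spikes
    n_laps = len(lap_spike_positions)

    peaks = _absorb_shallow_dips(rate, _local_peaks(rate, valid))
    fields: list[PlaceField] = []
    for p in peaks:
        i_lo, i_hi = _field_bounds(rate, valid, p)
        lo, hi = curve.edges[i_lo], curve.edges[i_hi]
        laps_with = sum(1 for sp in lap_spike_positions
                        if np.any((sp >= lo) & (sp < hi)))
        f = PlaceField(peak_pos=float(curve.centers[p]), peak_rate=float(rate[p]),
                       lo=float(lo), hi=float(hi), i_lo=i_lo, i_hi=i_hi,
                       n_laps_with_spikes=laps_with)
        need = max(5, int(np.ceil(0.2 * n_laps)))
        if laps_with < need:
            continue
        # local-SI significance over the field +- 50% of its width
        if shuffle_spike_positions is not None and lap_behav_positions is not None:
            w = hi - lo
            a, b = lo - 0.5 * w, hi + 0.5 * w
            sel = (curve.centers >= a) & (curve.centers < b) & valid
            if sel.sum() >= 2 and occ[sel].sum() > 0:
                behav = np.concatenate(lap_behav_positions)
                spk = np.concatenate(lap_spike_positions) if n_spikes else np.array([])

                def _local_si(spike_pos):
                    c = compute_tuning(spike_pos[(spike_pos >= a) & (spike_pos < b)],
                                       behav[(behav >= a) & (behav < b)],
                                       curve.edges[np.flatnonzero(sel)[0]:
                                                   np.flatnonzero(sel)[-1] + 2],
                                       POSITION_MIN_OCC,
                                       gaussian_kernel_1d(POSITION_SIGMA_BINS))
                    try:
                        return spatial_information(c.rate, c.occupancy, c.valid)
                    except ValueError:
                        return 0.0

                si_data = _local_si(spk)
                si_null = np.array([_local_si(s) for s in shuffle_spike_positions])
                f.local_si_percentile = float((si_null < si_data).mean())
                if f.local_si_percentile <= 0.95:
                    fields.append(f)  # kept as a candidate but not significant
                    continue
        f.significant = True
        fields.append(f)

    sig_fields = [f for f in fields if f.significant]

    try:
        si = spatial_information(rate, occ, valid)
    except ValueError:
        si = 0.0
    shuf_si = []
    for s in shuffle_curves:
        try:
            shuf_si.append(spatial_information(s, occ, valid & np.isfinite(s)))
        except ValueError:
            shuf_si.append(0.0)
    shuf_si = np.asarray(shuf_si)
    si_pct = float((shuf_si < si).mean())

    is_pc = (si_pct > 0.99 and si > SI_MIN and n_spikes >= MIN_SOLO_SPIKES
             and len(sig_fields) >= 1)

    # interfields: gaps between fields expanded by 50% of their width each side
    expanded = sorted((f.lo - 0.5 * f.width, f.hi + 0.5 * f.width)
                      for f in sig_fields)
    interfields = []
    lo_edge = float(curve.edges[0])
    for a, b in expanded:
        if a > lo_edge:
            interfields.append((lo_edge, float(a)))
        lo_edge = max(lo_edge, float(b))
    if lo_edge < curve.edges[-1]:
        interfields.append((lo_edge, float(curve.edges[-1])))

    return PlaceCellResult(fields=fields, interfields=interfields,
                           is_place_cell=bool(is_pc), si=float(si),
                           si_percentile=si_pct, n_spikes=n_spikes)


@dataclass
class MovementControlResult:
    variable: str
    slope_solo: float
    slope_cross: float
    sig_solo: bool
    sig_cross: bool
    applicable: bool = True

    @property
    def movement_modulated(self) -> bool:
        return (self.applicable and self.sig_solo and self.sig_cross
                and np.sign(self.slope_solo) == np.sign(self.slope_cross))


def _linear_slope(curve: TuningCurve1D) -> float:
    ok = curve.valid & np.isfinite(curve.rate)
    if ok.sum() < 2:
        return np.nan
    return float(np.polyfit(curve.centers[ok], curve.rate[ok], 1)[0])


def movement_control(spike_vals_solo: np.ndarray, behav_vals_solo: np.ndarray,
                     spike_vals_cross: np.ndarray, behav_vals_cross: np.ndarray,
                     shuffle_vals_solo: list[np.ndarray],
                     shuffle_vals_cross: list[np.ndarray],
                     variable: str = "S",
                     speed_range: tuple[float, float] | None = None) -> MovementControlResult:
    """Linear-fit significance of movement-variable tuning, solo and cross-over.

    Shuffle value lists hold one array of surrogate spike-time movement values
    per surrogate (session-concatenated circular shifts, done by the caller).
    A cell counts as movement-modulated only if the slope is significant in
    BOTH conditions with the same sign.
    """
    bw = 0.1 if variable == "S_Y" else 0.2
    if speed_range is None:
        lo = float(np.percentile(behav_vals_cross, 5))
        hi = float(np.percentile(behav_vals_cross, 95))
    else:
        lo, hi = speed_range
    if hi <= lo:
        return MovementControlResult(variable, np.nan, np.nan, False, False,
                                     applicable=False)
    edges = bin_edges(np.floor(lo / bw) * bw, np.ceil(hi / bw) * bw, bw)

    def _slope(spk, beh):
        sel_b = (beh >= lo) & (beh <= hi)
        sel_s = (spk >= lo) & (spk <= hi)
        c = compute_tuning(spk[sel_s], beh[sel_b], edges, DISTANCE_MIN_OCC,
                           boxcar_kernel(3), variable=variable)
        return _linear_slope(c)

    s_solo = _slope(spike_vals_solo, behav_vals_solo)
    s_cross = _slope(spike_vals_cross, behav_vals_cross)
    null_solo = np.asarray([_slope(v, behav_vals_solo) for v in shuffle_vals_solo])
    null_cross = np.asarray([_slope(v, behav_vals_cross) for v in shuffle_vals_cross])
    null_solo = null_solo[np.isfinite(null_solo)]
    null_cross = null_cross[np.isfinite(null_cross)]
    if (not np.isfinite(s_solo) or not np.isfinite(s_cross)
            or null_solo.size < 40 or null_cross.size < 40):
        return MovementControlResult(variable, s_solo, s_cross, False, False,
                                     applicable=False)
    sig_solo = bool(s_solo > np.percentile(null_solo, 97.5)
                    or s_solo < np.percentile(null_solo, 2.5))
    sig_cross = bool(s_cross > np.percentile(null_cross, 97.5)
                     or s_cross < np.percentile(null_cross, 2.5))
    return MovementControlResult(variable, s_solo, s_cross, sig_solo, sig_cross)


def laps_from_flights(flights, traj, spikes: np.ndarray):
    """Split spikes into per-flight (lap) position arrays.

    Returns (lap_spike_positions, lap_behav_positions).
    """
    lap_spikes, lap_behav = [], []
    for _, f in flights.iterrows():
        sl = slice(int(f.i_start), int(f.i_stop))
        sel = (spikes >= f.t_start) & (spikes <= f.t_end)
        lap_spikes.append(np.interp(spikes[sel], traj.t, traj.x))
        lap_behav.append(traj.x[sl])
    return lap_spikes, lap_behav
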