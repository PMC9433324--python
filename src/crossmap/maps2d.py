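"""2D distance-by-position firing-rate maps and cluster-based patch statistics."""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .behavior import CrossoverFlight
from .tuning import SAMPLE_DT
from .utils import bin_edges, digitize_clipped, smooth_valid_2d

BIN_2D = 3.0                 # m, both axes
SIGMA_2D_BINS = 1.5
MIN_OCC_2D = 0.2             # s; kept anyway if an adjacent bin was visited
PATCH_ALPHA = 0.005          # per-bin threshold for clustering (two-sided 0.5%)
PATCH_MIN_OCC_TOTAL = 2.0    # s in patch
PATCH_MIN_OCC_PER_BIN = 0.15
PATCH_MIN_SPIKES = 20        # enhancement only
PATCH_MIN_SPIKES_PER_BIN = 0.5
PATCH_MIN_FLIGHTS = 3
PEAK_RATE_MIN = 2.0          # Hz, cell admissibility


def map_edges(pos_lo: float = 0.0, pos_hi: float = 135.0,
              dist_range: float = 40.5) -> tuple[np.ndarray, np.ndarray]:
    """3 m grid: position rows, distance columns (distance spans +-40.5 m so
    27 bins tile the +-40 m window symmetrically)."""
    return bin_edges(pos_lo, pos_hi, BIN_2D), bin_edges(-dist_range, dist_range, BIN_2D)


@dataclass
class RateMap2D:
    """Smoothed occupancy-normalised 2D map; rows = position, cols = distance."""

    rate: np.ndarray
    spikes: np.ndarray              # raw counts
    occupancy: np.ndarray           # raw seconds
    valid: np.ndarray
    pos_edges: np.ndarray
    dist_edges: np.ndarray

    @property
    def peak_rate(self) -> float:
        return float(np.nanmax(self.rate)) if np.isfinite(self.rate).any() else 0.0


def _bin_xd(x: np.ndarray, d: np.ndarray, pos_edges: np.ndarray,
            dist_edges: np.ndarray) -> np.ndarray:
    ip = digitize_clipped(x, pos_edges)
    id_ = digitize_clipped(d, dist_edges)
    ok = (ip >= 0) & (id_ >= 0)
    grid = np.zeros((pos_edges.size - 1, dist_edges.size - 1))
    np.add.at(grid, (ip[ok], id_[ok]), 1.0)
    return grid


def rate_map_2d(spike_x: np.ndarray, spike_d: np.ndarray,
                behav_x: np.ndarray, behav_d: np.ndarray,
                pos_edges: np.ndarray | None = None,
                dist_edges: np.ndarray | None = None,
                dt: float = SAMPLE_DT) -> RateMap2D:
    """Smoothed 2D rate map with the low-occupancy / visited-neighbour rule."""
    if pos_edges is None or dist_edges is None:
        pe, de = map_edges()
        pos_edges = pos_edges if pos_edges is not None else pe
        dist_edges = dist_edges if dist_edges is not None else de
    occ = _bin_xd(behav_x, behav_d, pos_edges, dist_edges) * dt
    spk = _bin_xd(spike_x, spike_d, pos_edges, dist_edges)
    # low-occupancy bins survive only if an adjacent bin was visited
    visited = occ > 0
    low = (occ < MIN_OCC_2D) & visited
    has_neigh = ndimage.binary_dilation(visited, structure=np.array(
        [[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool))
    valid = (occ >= MIN_OCC_2D) | (low & has_neigh)
    sm_spk = smooth_valid_2d(spk, valid, SIGMA_2D_BINS)
    sm_occ = smooth_valid_2d(occ, valid, SIGMA_2D_BINS)
    rate = np.full(occ.shape, np.nan)
    ok = valid & np.isfinite(sm_occ) & (sm_occ > 0)
    rate[ok] = sm_spk[ok] / sm_occ[ok]
    return RateMap2D(rate=rate, spikes=spk, occupancy=occ, valid=valid,
                     pos_edges=pos_edges, dist_edges=dist_edges)


def crossover_map(spike_times: np.ndarray, crossovers: list[CrossoverFlight],
                  pos_edges: np.ndarray | None = None,
                  dist_edges: np.ndarray | None = None) -> RateMap2D:
    """Convenience: 2D map of one cell over a set of cross-over flights."""
    sx, sd, bx, bd = [], [], [], []
    for c in crossovers:
        sel = (spike_times >= c.t[0]) & (spike_times <= c.t[-1])
        sx.append(np.interp(spike_times[sel], c.t, c.x))
        sd.append(np.interp(spike_times[sel], c.t, c.d))
        bx.append(c.x)
        bd.append(c.d)
    cat = lambda parts: np.concatenate(parts) if parts else np.array([])
    return rate_map_2d(cat(sx), cat(sd), cat(bx), cat(bd),
                       pos_edges=pos_edges, dist_edges=dist_edges)


@dataclass
class Patch:
    bins: np.ndarray                # (k, 2) array of (row, col) indices
    polarity: str                   # 'enhancement' | 'suppression'
    score: float
    percentile: float = np.nan
    passes_criteria: bool = True
    criteria_flags: dict = dfield(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.bins.shape[0]


def _clusters_and_scores(p_map: np.ndarray, valid: np.ndarray,
                         connectivity: int = 4):
    """Threshold a per-bin percentile map into polarity clusters with scores."""
    structure = (np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
                 if connectivity == 4 else np.ones((3, 3), dtype=bool))
    out = []
    with np.errstate(divide="ignore"):
        surprise_enh = -np.log10(np.clip(1.0 - p_map, 1e-300, None))
        surprise_sup = -np.log10(np.clip(p_map, 1e-300, None))
    for polarity, mask, surprise in (
            ("enhancement", (p_map > 1.0 - PATCH_ALPHA) & valid, surprise_enh),
            ("suppression", (p_map < PATCH_ALPHA) & valid, surprise_sup)):
        labels, n = ndimage.label(mask, structure=structure)
        for lab in range(1, n + 1):
            sel = labels == lab
            score = float(surprise[sel].sum())
            bins = np.argwhere(sel)
            out.append(Patch(bins=bins, polarity=polarity, score=score))
    return out


def _percentile_maps(data: np.ndarray, stack: np.ndarray) -> np.ndarray:
    """Midpoint-tie percentile of the data map vs the shuffle stack.

    P is clipped to [0.5/n, (n-0.5)/n] — the exact range attainable by a
    shuffle map ranked within its own stack — so a data bin above every
    surrogate carries the same (finite) surprise a top-ranked surrogate bin
    would. Without the clip the data's surprise would be unbounded and the
    max-cluster null could never match it.
    """
    n = stack.shape[0]
    below = np.nansum(stack < data[None], axis=0)
    equal = np.nansum(stack == data[None], axis=0)
    p = (below + 0.5 * equal) / n
    return np.clip(p, 0.5 / n, (n - 0.5) / n)


def patch_analysis(data_map: RateMap2D, shuffle_rates: np.ndarray,
                   spike_flight_bins: list[np.ndarray] | None = None,
                   connectivity: int = 4,
                   min_shuffles: int = 1000) -> list[Patch]:
    """Cluster-based patch significance against solo-projection shuffle maps.

    ``shuffle_rates`` is an (n, rows, cols) stack sharing the data grid.
    ``spike_flight_bins`` holds one (k, 2) array of spike (row, col) bins per
    cross-over flight, used for the flights-with-spikes criterion.
    Cells whose map peaks below 2 Hz are not admissible and return [].
    """
    if shuffle_rates.shape[0] < min_shuffles:
        raise ValueError(f"need >= {min_shuffles} shuffle maps, "
                         f"got {shuffle_rates.shape[0]}")
    if data_map.peak_rate < PEAK_RATE_MIN:
        return []
    valid = data_map.valid & np.isfinite(data_map.rate)
    p_data = _percentile_maps(np.where(valid, data_map.rate, np.nan), shuffle_rates)
    clusters = _clusters_and_scores(p_data, valid, connectivity)
    if not clusters:
        return []

    # null distribution: max cluster score per shuffle map, per polarity;
    # midpoint-tie percentiles for all shuffles at once via average ranks
    n = shuffle_rates.shape[0]
    ranks = rankdata(np.where(np.isfinite(shuffle_rates), shuffle_rates, -np.inf),
                     axis=0, method="average")
    p_stack = (ranks - 0.5) / n
    null_max = {"enhancement": np.zeros(n), "suppression": np.zeros(n)}
    for i in range(n):
        for cl in _clusters_and_scores(p_stack[i], valid, connectivity):
            if cl.score > null_max[cl.polarity][i]:
                null_max[cl.polarity][i] = cl.score

    kept = []
    for cl in clusters:
        null = null_max[cl.polarity]
        cl.percentile = float((null < cl.score).mean())
        if cl.percentile <= 0.95:
            continue
        rows, cols = cl.bins[:, 0], cl.bins[:, 1]
        occ_total = float(data_map.occupancy[rows, cols].sum())
        occ_per_bin = occ_total / cl.n_bins
        flags = {
            "occ_total": occ_total >= PATCH_MIN_OCC_TOTAL,
            "occ_per_bin": occ_per_bin >= PATCH_MIN_OCC_PER_BIN,
        }
        if cl.polarity == "enhancement":
            spk_total = float(data_map.spikes[rows, cols].sum())
            flags["spikes_total"] = spk_total >= PATCH_MIN_SPIKES
            flags["spikes_per_bin"] = spk_total / cl.n_bins >= PATCH_MIN_SPIKES_PER_BIN
            if spike_flight_bins is not None:
                member = set(map(tuple, cl.bins.tolist()))
                n_flights = sum(
                    1 for fb in spike_flight_bins
                    if any(tuple(b) in member for b in fb.tolist()))
                flags["flights_with_spikes"] = n_flights >= PATCH_MIN_FLIGHTS
        cl.criteria_flags = flags
        cl.passes_criteria = all(flags.values())
        if cl.passes_criteria:
            kept.append(cl)
    return kept


def shuffle_map_stack(ensemble_spike_xd: list[tuple[np.ndarray, np.ndarray]],
                      behav_x: np.ndarray, behav_d: np.ndarray,
                      pos_edges: np.ndarray, dist_edges: np.ndarray,
                      dt: float = SAMPLE_DT) -> np.ndarray:
    """Rasterise an ensemble of surrogate spike (x, d) sets into smoothed maps
    sharing the data occupancy."""
    occ = _bin_xd(behav_x, behav_d, pos_edges, dist_edges) * dt
    visited = occ > 0
    low = (occ < MIN_OCC_2D) & visited
    has_neigh = ndimage.binary_dilation(visited, structure=np.array(
        [[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool))
    valid = (occ >= MIN_OCC_2D) | (low & has_neigh)
    sm_occ = smooth_valid_2d(occ, valid, SIGMA_2D_BINS)
    out = np.full((len(ensemble_spike_xd),) + occ.shape, np.nan)
    for i, (sx, sd) in enumerate(ensemble_spike_xd):
        spk = _bin_xd(sx, sd, pos_edges, dist_edges)
        sm_spk = smooth_valid_2d(spk, valid, SIGMA_2D_BINS)
        ok = valid & np.isfinite(sm_occ) & (sm_occ > 0)
        out[i][ok] = sm_spk[ok] / sm_occ[ok]
    return out
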