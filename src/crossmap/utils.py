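"""Shared numeric helpers: seeded substreams, binning, validity-aware smoothing."""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def spawn_rngs(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """Fan a single seed out to named, independent substreams.

    The mapping is deterministic in both the seed and the order of ``names``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def bin_edges(lo: float, hi: float, width: float) -> np.ndarray:
    """Half-open bins [lo, hi) tiled at ``width``; the last edge lands on ``hi``
    only when the range is an exact multiple of the width."""
    n = int(round((hi - lo) / width))
    if not np.isclose(lo + n * width, hi):
        n = int(np.floor((hi - lo) / width))
    return lo + width * np.arange(n + 1)


def bin_centers(edges: np.ndarray) -> np.ndarray:
    return 0.5 * (edges[:-1] + edges[1:])


def digitize_clipped(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin indices for values inside [edges[0], edges[-1]); -1 for outside."""
    idx = np.searchsorted(edges, values, side="right") - 1
    idx[(values < edges[0]) | (values >= edges[-1])] = -1
    return idx


def gaussian_kernel_1d(sigma_bins: float, radius_factor: float = 4.0) -> np.ndarray:
    radius = max(1, int(np.ceil(radius_factor * sigma_bins)))
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma_bins) ** 2)
    return k / k.sum()


def smooth_valid_1d(values: np.ndarray, valid: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Validity-aware smoothing with sender-side kernel renormalisation.

    Each source bin's kernel is renormalised over the valid bins it can reach
    before its mass is spread, so totals over valid bins are conserved exactly
    and edges carry no bias. Invalid bins stay NaN. ``values`` may be a stack
    (n, nbins) sharing one ``valid`` mask.
    """
    values = np.asarray(values, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    den = ndimage.convolve1d(valid.astype(float), kernel, mode="constant", cval=0.0)
    src = np.where(valid & (den > 0), values / np.where(den > 0, den, 1.0), 0.0)
    out = ndimage.convolve1d(src, kernel, axis=-1, mode="constant", cval=0.0)
    out[..., ~valid] = np.nan
    return out


def boxcar_kernel(n: int = 3) -> np.ndarray:
    return np.full(n, 1.0 / n)


def smooth_valid_2d(values: np.ndarray, valid: np.ndarray, sigma_bins: float) -> np.ndarray:
    """2D Gaussian smoothing restricted to the valid mask, sender-normalised
    (see :func:`smooth_valid_1d`)."""
    den = ndimage.gaussian_filter(valid.astype(float), sigma_bins,
                                  mode="constant", cval=0.0)
    src = np.where(valid & (den > 0), values / np.where(den > 0, den, 1.0), 0.0)
    out = ndimage.gaussian_filter(src, sigma_bins, mode="constant", cval=0.0)
    out[~valid] = np.nan
    return out


def percentile_rank(data: np.ndarray, surrogate: np.ndarray, axis: int = 0) -> np.ndarray:
    """Fraction of surrogate values strictly below ``data``, with midpoint tie
    handling: P = (#below + 0.5 * #equal) / n."""
    below = (surrogate < data).sum(axis=axis)
    equal = (surrogate == data).sum(axis=axis)
    n = surrogate.shape[axis]
    return (below + 0.5 * equal) / n


def contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs in a 1D boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    runs = []
    in_run = False
    start = 0
    for i, m in enumerate(mask):
        if m and not in_run:
            in_run, start = True, i
        elif not m and in_run:
            in_run = False
            runs.append((start, i))
    if in_run:
        runs.append((start, len(mask)))
    return runs
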