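"""Generative model of 2D distance-by-position firing maps and trial spike counts.

A model neuron has multiple place fields laid on a linear track. Each field is
assigned one of ``n_dis`` distance-modulation profiles, where ``n_dis`` is tied
to the number of fields by the non-separability knob ``x_sep``:
``n_dis = ceil(n_field * x_sep)``. Maps may additionally carry a firing
"hotspot" away from fields, with probability ``(x_sep - 0.2) / 0.8``.

The map value ``f(x_D, x_P)`` is a unitless multiplier of the in-field expected
spike count ``m0``: 1 inside an unmodulated field, 0 outside fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np

from ..utils import as_rng, bin_centers, bin_edges


@dataclass(frozen=True)
class NeuronModelConfig:
    """Parameters of the generative neuron model (gamma laws use shape/scale)."""

    k_coverage: float = 1.76
    theta_coverage: float = 0.18          # fraction of track
    coverage_cap: float = 0.8
    k_field_size: float = 4.62
    theta_field_size: float = 2.68        # metres
    x_sep: float = 1.0                    # non-separability knob, 0.2..1.0
    p_enhance: float = 0.38
    p_suppress: float = 0.20
    p_none: float = 0.42
    profile_center_mu: float = 0.0        # metres of interbat distance
    profile_center_sigma: float = 16.8
    profile_width_lo: float = 4.3
    profile_width_hi: float = 12.9
    k_enhance: float = 9.98
    theta_enhance: float = 0.32
    k_suppress: float = 0.39
    theta_suppress: float = 0.17
    m0: float = 5.0                       # expected in-field spike count
    track_length: float = 130.0
    distance_range: float = 40.0          # map spans +-distance_range
    grid_bin: float = 0.5
    max_placement_retries: int = 1000

    @property
    def hotspot_prob(self) -> float:
        return (self.x_sep - 0.2) / 0.8

    def validate(self) -> None:
        if not math.isclose(self.p_enhance + self.p_suppress + self.p_none, 1.0):
            raise ValueError("modulation probabilities must sum to 1")
        for name in ("k_coverage", "theta_coverage", "k_field_size",
                     "theta_field_size", "k_enhance", "theta_enhance",
                     "k_suppress", "theta_suppress"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.hotspot_prob <= 1.0 + 1e-12):
            raise ValueError("x_sep must lie in [0.2, 1.0]")


@dataclass(frozen=True)
class TrialSimConfig:
    """Kinematics and evaluation grid of the simulated decoding trials."""

    v: float = 8.0                # flight speed, m/s, each bat
    delta_t: float = 0.5          # integration window, s
    n_distances: int = 41
    n_positions: int = 11
    distance_range: float = 40.0
    track_length: float = 130.0
    n_populations: int = 250
    n_repeats: int = 5
    N_grid: tuple[int, ...] = tuple(range(20, 201, 20))
    integration_step: float = 1e-3

    @property
    def x0D_grid(self) -> np.ndarray:
        return np.linspace(-self.distance_range, self.distance_range, self.n_distances)

    @property
    def x0P_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.track_length, self.n_positions)


@dataclass
class DistanceProfile:
    """One distance-modulation profile: a raised-cosine gain bump.

    ``gain(x_D) = 1 + (gain - 1) * 0.5 * (1 + cos(pi (x_D - center) / width))``
    for ``|x_D - center| < width`` and 1 outside — ``width`` is the half-width
    of the compact support.
    """

    kind: str            # 'enhance' | 'suppress' | 'none'
    center: float = 0.0
    width: float = 0.0
    gain: float = 1.0

    def evaluate(self, x_d: np.ndarray) -> np.ndarray:
        g = np.ones_like(x_d, dtype=float)
        if self.kind == "none" or self.width <= 0:
            return g
        u = (x_d - self.center) / self.width
        inside = np.abs(u) < 1.0
        bump = 0.5 * (1.0 + np.cos(np.pi * u[inside]))
        g[inside] = 1.0 + (self.gain - 1.0) * bump
        return g


@dataclass
class ModelMap2D:
    """A simulated neuron's 2D distance-by-position map on a regular grid.

    ``rate_grid[i_pos, i_dist]`` is a non-negative multiplier of ``m0``.
    """

    rate_grid: np.ndarray
    pos_edges: np.ndarray
    dist_edges: np.ndarray
    fields: list[tuple[float, float, int]] = dfield(default_factory=list)
    profiles: list[DistanceProfile] = dfield(default_factory=list)
    hotspot: tuple[tuple[float, float], float] | None = None
    x_sep: float = 1.0
    m0: float = 5.0

    @property
    def n_field(self) -> int:
        return len(self.fields)

    @property
    def n_dis(self) -> int:
        return len(self.profiles)

    @property
    def position_profile(self) -> np.ndarray:
        """Pure position tuning: map value with every distance profile at gain 1."""
        prof = np.zeros(self.rate_grid.shape[0])
        centers = bin_centers(self.pos_edges)
        for lo, hi, _ in self.fields:
            prof[(centers >= lo) & (centers < hi)] = 1.0
        return prof

    def lookup(self, x_d: np.ndarray, x_p: np.ndarray) -> np.ndarray:
        """Grid lookup with clamping to the map's support (piecewise constant)."""
        npos, ndist = self.rate_grid.shape
        bw_p = self.pos_edges[1] - self.pos_edges[0]
        bw_d = self.dist_edges[1] - self.dist_edges[0]
        ip = np.clip(((np.asarray(x_p) - self.pos_edges[0]) / bw_p).astype(int), 0, npos - 1)
        idx = np.clip(((np.asarray(x_d) - self.dist_edges[0]) / bw_d).astype(int), 0, ndist - 1)
        return self.rate_grid[ip, idx]


def _sample_profile(cfg: NeuronModelConfig, kind: str, rng: np.random.Generator) -> DistanceProfile:
    center = rng.normal(cfg.profile_center_mu, cfg.profile_center_sigma)
    width = rng.uniform(cfg.profile_width_lo, cfg.profile_width_hi)
    if kind == "enhance":
        gain = rng.gamma(cfg.k_enhance, cfg.theta_enhance)
    elif kind == "suppress":
        gain = rng.gamma(cfg.k_suppress, cfg.theta_suppress)
    else:
        return DistanceProfile(kind="none")
    return DistanceProfile(kind=kind, center=center, width=width, gain=gain)


def _place_fields(sizes: np.ndarray, cfg: NeuronModelConfig,
                  rng: np.random.Generator) -> list[tuple[float, float]]:
    """Uniform non-overlapping placement with boundary truncation.

    Few fields are placed by rejection (exactly uniform centers); dense
    configurations fall back to a uniform partition of the free space into
    inter-field gaps, with one mean field size of overhang allowed at each
    boundary before truncation.
    """
    L = cfg.track_length
    n = sizes.size
    n_tries = cfg.max_placement_retries if sizes.sum() < 0.5 * L else 0
    for _ in range(n_tries):
        centers = rng.uniform(0.0, L, size=n)
        lo = centers - sizes / 2.0
        hi = centers + sizes / 2.0
        order = np.argsort(lo)
        if np.all(lo[order][1:] >= hi[order][:-1]):
            return [(max(0.0, a), min(L, b)) for a, b in zip(lo, hi)]
    ext = float(np.mean(sizes))
    free = L + 2.0 * ext - float(sizes.sum())
    if free <= 0:
        raise RuntimeError(
            f"cannot place {n} fields totalling {sizes.sum():.1f} m on a "
            f"{L:.0f} m track (coverage too high for the field count)")
    gaps = rng.dirichlet(np.ones(n + 1)) * free
    shuffled = sizes[rng.permutation(n)]
    bounds = []
    pos = -ext
    for g, size in zip(gaps, shuffled):
        pos += g
        lo, hi = pos, pos + size
        pos = hi
        lo_t, hi_t = max(0.0, lo), min(L, hi)
        if hi_t - lo_t > cfg.grid_bin:
            bounds.append((lo_t, hi_t))
    return bounds


def build_neuron_map(cfg: NeuronModelConfig, rng) -> ModelMap2D:
    """Draw one model neuron and rasterise its 2D map on the configured grid."""
    cfg.validate()
    rng = as_rng(rng)

    coverage = rng.gamma(cfg.k_coverage, cfg.theta_coverage)
    while coverage > cfg.coverage_cap:
        coverage = rng.gamma(cfg.k_coverage, cfg.theta_coverage)
    target = coverage * cfg.track_length

    sizes: list[float] = []
    while sum(sizes) < target:
        sizes.append(rng.gamma(cfg.k_field_size, cfg.theta_field_size))
    sizes_arr = np.asarray(sizes)
    bounds = _place_fields(sizes_arr, cfg, rng)

    n_field = len(bounds)
    n_dis = math.ceil(n_field * cfg.x_sep)
    kinds = rng.choice(["enhance", "suppress", "none"], size=n_dis,
                       p=[cfg.p_enhance, cfg.p_suppress, cfg.p_none])
    profiles = [_sample_profile(cfg, k, rng) for k in kinds]

    # every profile used at least once; extra fields get a uniform draw
    assignment = np.concatenate([
        rng.permutation(n_dis),
        rng.integers(0, n_dis, size=n_field - n_dis),
    ]) if n_field > 0 else np.empty(0, dtype=int)

    pos_edges = bin_edges(0.0, cfg.track_length, cfg.grid_bin)
    dist_edges = bin_edges(-cfg.distance_range, cfg.distance_range, cfg.grid_bin)
    p_centers = bin_centers(pos_edges)
    d_centers = bin_centers(dist_edges)

    grid = np.zeros((p_centers.size, d_centers.size))
    fields = []
    for (lo, hi), prof_id in zip(bounds, assignment):
        rows = (p_centers >= lo) & (p_centers < hi)
        grid[rows, :] = profiles[prof_id].evaluate(d_centers)[None, :]
        fields.append((lo, hi, int(prof_id)))

    hotspot = None
    if rng.random() < cfg.hotspot_prob:
        hs = _sample_profile(cfg, "enhance", rng)
        pos_center = rng.uniform(0.0, cfg.track_length)
        pos_width = rng.uniform(cfg.profile_width_lo, cfg.profile_width_hi)
        up = (p_centers - pos_center) / pos_width
        ud = (d_centers - hs.center) / hs.width
        bump_p = np.where(np.abs(up) < 1, 0.5 * (1 + np.cos(np.pi * np.clip(up, -1, 1))), 0.0)
        bump_d = np.where(np.abs(ud) < 1, 0.5 * (1 + np.cos(np.pi * np.clip(ud, -1, 1))), 0.0)
        hot = hs.gain * np.outer(bump_p, bump_d)
        grid = np.maximum(grid, hot)
        hotspot = ((pos_center, hs.center), hs.gain)

    return ModelMap2D(rate_grid=grid, pos_edges=pos_edges, dist_edges=dist_edges,
                      fields=fields, profiles=profiles, hotspot=hotspot,
                      x_sep=cfg.x_sep, m0=cfg.m0)


def build_population(cfg: NeuronModelConfig, n: int, rng) -> list[ModelMap2D]:
    rng = as_rng(rng)
    return [build_neuron_map(cfg, rng) for _ in range(n)]


def _rasterise(cfg: NeuronModelConfig, bounds, profiles, assignment,
               hotspot_draw) -> ModelMap2D:
    pos_edges = bin_edges(0.0, cfg.track_length, cfg.grid_bin)
    dist_edges = bin_edges(-cfg.distance_range, cfg.distance_range, cfg.grid_bin)
    p_centers = bin_centers(pos_edges)
    d_centers = bin_centers(dist_edges)
    grid = np.zeros((p_centers.size, d_centers.size))
    fields = []
    for (lo, hi), prof_id in zip(bounds, assignment):
        rows = (p_centers >= lo) & (p_centers < hi)
        grid[rows, :] = profiles[prof_id].evaluate(d_centers)[None, :]
        fields.append((lo, hi, int(prof_id)))
    hotspot = None
    if hotspot_draw is not None:
        hs, pos_center, pos_width = hotspot_draw
        up = (p_centers - pos_center) / pos_width
        ud = (d_centers - hs.center) / hs.width
        bump_p = np.where(np.abs(up) < 1,
                          0.5 * (1 + np.cos(np.pi * np.clip(up, -1, 1))), 0.0)
        bump_d = np.where(np.abs(ud) < 1,
                          0.5 * (1 + np.cos(np.pi * np.clip(ud, -1, 1))), 0.0)
        grid = np.maximum(grid, hs.gain * np.outer(bump_p, bump_d))
        hotspot = ((pos_center, hs.center), hs.gain)
    return ModelMap2D(rate_grid=grid, pos_edges=pos_edges, dist_edges=dist_edges,
                      fields=fields, profiles=list(profiles), hotspot=hotspot,
                      x_sep=cfg.x_sep, m0=cfg.m0)


def build_matched_populations(cfg: NeuronModelConfig,
                              x_sep_levels: tuple[float, ...], n: int,
                              rng) -> dict[float, list[ModelMap2D]]:
    """Populations sharing field layouts and modulation draws across x_sep.

    Per neuron, the place-field layout, the pool of distance profiles and the
    hotspot parameters are drawn once; each non-separability level only
    changes how many distinct profiles (n_dis = ceil(n_field * x_sep)) are
    spread over the fields and whether the shared hotspot is expressed —
    populations with the same distance modulations, differing only in
    separability.
    """
    rng = as_rng(rng)
    cfg.validate()
    out: dict[float, list[ModelMap2D]] = {x: [] for x in x_sep_levels}
    for _ in range(n):
        coverage = rng.gamma(cfg.k_coverage, cfg.theta_coverage)
        while coverage > cfg.coverage_cap:
            coverage = rng.gamma(cfg.k_coverage, cfg.theta_coverage)
        target = coverage * cfg.track_length
        sizes: list[float] = []
        while sum(sizes) < target:
            sizes.append(rng.gamma(cfg.k_field_size, cfg.theta_field_size))
        bounds = _place_fields(np.asarray(sizes), cfg, rng)
        n_field = len(bounds)
        kinds = rng.choice(["enhance", "suppress", "none"], size=max(n_field, 1),
                           p=[cfg.p_enhance, cfg.p_suppress, cfg.p_none])
        profiles = [_sample_profile(cfg, k, rng) for k in kinds]
        perm = rng.permutation(n_field)
        hs = _sample_profile(cfg, "enhance", rng)
        hs_pos = rng.uniform(0.0, cfg.track_length)
        hs_width = rng.uniform(cfg.profile_width_lo, cfg.profile_width_hi)
        u_hot = rng.random()
        for x_sep in x_sep_levels:
            lvl_cfg = NeuronModelConfig(**{**cfg.__dict__, "x_sep": x_sep})
            n_dis = max(1, math.ceil(n_field * x_sep))
            assignment = np.empty(n_field, dtype=int)
            assignment[perm] = np.arange(n_field) % n_dis
            hot = (hs, hs_pos, hs_width) if u_hot < lvl_cfg.hotspot_prob else None
            out[x_sep].append(_rasterise(lvl_cfg, bounds, profiles[:max(n_dis, 1)],
                                         assignment, hot))
    return out


def _path_mean(map2d: ModelMap2D, x0d, x0p, tcfg: TrialSimConfig) -> np.ndarray:
    """Trapezoidal time-average of the map along the trial path.

    The path advances at 2v along the distance axis (both bats closing) and at
    v along position; points leaving the grid are clamped to the edge bins.
    """
    n_steps = max(2, int(round(tcfg.delta_t / tcfg.integration_step)) + 1)
    t = np.linspace(0.0, tcfg.delta_t, n_steps)
    x0d = np.atleast_1d(np.asarray(x0d, dtype=float))
    x0p = np.atleast_1d(np.asarray(x0p, dtype=float))
    xd = x0d[:, None] + 2.0 * tcfg.v * t[None, :]
    xp = x0p[:, None] + tcfg.v * t[None, :]
    vals = map2d.lookup(xd, xp)
    return np.trapezoid(vals, t, axis=1) / tcfg.delta_t


def simulate_trial_counts(map2d: ModelMap2D, trial: tuple[float, float],
                          tcfg: TrialSimConfig, rng) -> tuple[int, float]:
    """Poisson spike count of one neuron on one trial; returns (count, mean).

    The expected count is ``m0 / dt * integral f(x0D + 2vt, x0P + vt) dt``.
    """
    rng = as_rng(rng)
    x0d, x0p = trial
    if not (-tcfg.distance_range <= x0d <= tcfg.distance_range):
        raise ValueError("trial start distance outside the grid")
    if not (0.0 <= x0p <= tcfg.track_length):
        raise ValueError("trial start position outside the grid")
    m = float(map2d.m0 * _path_mean(map2d, x0d, x0p, tcfg)[0])
    if not np.isfinite(m):
        raise ValueError("non-finite expected count")
    return int(rng.poisson(m)), m


def expected_counts_grid(maps: list[ModelMap2D], tcfg: TrialSimConfig) -> np.ndarray:
    """Expected counts for every (x0D, x0P) grid combination; shape (n_trials, N).

    Trials enumerate the grid with position varying fastest (distance-major
    order), so argmax ties resolve to the smallest distance, then position.
    """
    dd, pp = np.meshgrid(tcfg.x0D_grid, tcfg.x0P_grid, indexing="ij")
    x0d = dd.ravel()
    x0p = pp.ravel()
    out = np.empty((x0d.size, len(maps)))
    for j, m in enumerate(maps):
        out[:, j] = m.m0 * _path_mean(m, x0d, x0p, tcfg)
    return out
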