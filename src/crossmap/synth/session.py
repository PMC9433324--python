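"""Session-level synthesis: paired shuttle flights, spike trains and clicks.

Two bats shuttle between landing balls at the ends of a long tunnel with
per-flight constant speed and randomised rests, which staggers take-offs and
spreads cross-over positions roughly uniformly over the central span.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from ..utils import as_rng, bin_centers
from .model import ModelMap2D

GT_RATE = 100.0  # ground-truth kinematics sampling, Hz


@dataclass(frozen=True)
class SessionConfig:
    tunnel_length: float = 135.0
    ball_low: float = 5.0
    ball_high: float = 130.0
    n_flights_per_direction: int = 30
    speed_mean: float = 8.0
    speed_sd: float = 0.5
    sample_rate_raw: float = 16.0
    lateral_noise_sd: float = 0.05
    rest_duration_law: str = "uniform:1:35"   # seconds
    click_base_rate: float = 2.5              # Hz, solo
    click_rise_factor: float = 4.0
    click_rise_onset: float = -20.0           # metres (approaching = negative)
    click_ramp_len: float = 5.0               # metres to reach full factor
    click_pair_gap: float = 0.025             # s between the two clicks of a pair

    def draw_rest(self, rng: np.random.Generator) -> float:
        parts = self.rest_duration_law.split(":")
        if parts[0] == "uniform":
            return rng.uniform(float(parts[1]), float(parts[2]))
        if parts[0] == "exponential":
            return rng.exponential(float(parts[1]))
        if parts[0] == "fixed":
            return float(parts[1])
        raise ValueError(f"unknown rest duration law: {self.rest_duration_law}")


@dataclass
class BatGroundTruth:
    """Piecewise-linear ground-truth motion of one bat."""

    knots_t: np.ndarray
    knots_x: np.ndarray
    flights: pd.DataFrame     # t_start, t_end, direction

    def x_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.knots_t, self.knots_x)

    def flying_at(self, t: np.ndarray) -> np.ndarray:
        mask = np.zeros(t.shape, dtype=bool)
        for _, f in self.flights.iterrows():
            mask |= (t >= f.t_start) & (t <= f.t_end)
        return mask

    def direction_at(self, t: np.ndarray) -> np.ndarray:
        out = np.zeros(t.shape)
        for _, f in self.flights.iterrows():
            out[(t >= f.t_start) & (t <= f.t_end)] = f.direction
        return out


@dataclass
class SyntheticSession:
    cfg: SessionConfig
    bats: list[BatGroundTruth]
    raw: list[pd.DataFrame]               # per bat: t, x, y at sample_rate_raw
    events: pd.DataFrame                  # cross-over log: t_cross, x_cross
    duration: float
    t_grid: np.ndarray = dfield(repr=False, default=None)

    def kinematics(self, bat: int) -> dict[str, np.ndarray]:
        """Noise-free 100 Hz kinematics of one bat (ground truth)."""
        t = self.t_grid
        me, other = self.bats[bat], self.bats[1 - bat]
        x = me.x_at(t)
        xo = other.x_at(t)
        vx = np.gradient(x, t) if t.size > 1 else np.zeros_like(x)
        return {
            "t": t,
            "x": x,
            "x_other": xo,
            "vx": vx,
            "flying": me.flying_at(t),
            "direction": me.direction_at(t),
            "other_flying": other.flying_at(t),
        }


def _build_bat(cfg: SessionConfig, rng: np.random.Generator,
               initial_delay: float, start_high: bool = False) -> BatGroundTruth:
    t = initial_delay
    x = cfg.ball_high if start_high else cfg.ball_low
    knots_t, knots_x = [0.0, t], [x, x]
    rows = []
    n_total = 2 * cfg.n_flights_per_direction
    for _ in range(n_total):
        direction = 1 if x == cfg.ball_low else -1
        target = cfg.ball_high if direction == 1 else cfg.ball_low
        speed = max(2.5, rng.normal(cfg.speed_mean, cfg.speed_sd))
        dur = abs(target - x) / speed
        rows.append({"t_start": t, "t_end": t + dur, "direction": direction,
                     "speed": speed})
        t += dur
        x = target
        knots_t.append(t)
        knots_x.append(x)
        rest = cfg.draw_rest(rng)
        t += rest
        knots_t.append(t)
        knots_x.append(x)
    return BatGroundTruth(np.asarray(knots_t), np.asarray(knots_x),
                          pd.DataFrame(rows))


def simulate_session(scfg: SessionConfig, rng) -> SyntheticSession:
    """Generate one paired session: raw trajectory samples plus an event log."""
    rng = as_rng(rng)
    if scfg.n_flights_per_direction <= 0:
        empty = pd.DataFrame(columns=["t_start", "t_end", "direction", "speed"])
        bats = [BatGroundTruth(np.array([0.0]), np.array([scfg.ball_low]), empty.copy())
                for _ in range(2)]
        raw = [pd.DataFrame({"t": [], "x": [], "y": []}) for _ in range(2)]
        events = pd.DataFrame(columns=["t_cross", "x_cross"])
        return SyntheticSession(scfg, bats, raw, events, 0.0, np.array([]))

    pass_time = (scfg.ball_high - scfg.ball_low) / scfg.speed_mean
    delays = [rng.uniform(0, 2.0), rng.uniform(0, 2.0 * pass_time)]
    # bat 1 starts from the opposite ball so most simultaneous passes are
    # opposite-direction (cross-overs) rather than same-direction
    bats = [_build_bat(scfg, rng, delays[0], start_high=False),
            _build_bat(scfg, rng, delays[1], start_high=True)]
    duration = float(max(b.knots_t[-1] for b in bats))
    t_grid = np.arange(0.0, duration, 1.0 / GT_RATE)

    # raw samples at the tag rate with lateral noise
    raw = []
    for b in bats:
        tr = np.arange(0.0, duration, 1.0 / scfg.sample_rate_raw)
        raw.append(pd.DataFrame({
            "t": tr,
            "x": b.x_at(tr),
            "y": rng.normal(0.0, scfg.lateral_noise_sd, size=tr.size),
        }))

    # cross-over event log from ground truth
    x0, x1 = bats[0].x_at(t_grid), bats[1].x_at(t_grid)
    d01 = x1 - x0
    f0, f1 = bats[0].flying_at(t_grid), bats[1].flying_at(t_grid)
    dir0, dir1 = bats[0].direction_at(t_grid), bats[1].direction_at(t_grid)
    opposite = f0 & f1 & (dir0 * dir1 == -1)
    sign_change = np.sign(d01[:-1]) * np.sign(d01[1:]) < 0
    idx = np.flatnonzero(sign_change & opposite[:-1] & opposite[1:])
    rows = []
    for i in idx:
        frac = d01[i] / (d01[i] - d01[i + 1])
        tc = t_grid[i] + frac / GT_RATE
        rows.append({"t_cross": tc, "x_cross": float(bats[0].x_at(np.array([tc]))[0])})
    events = pd.DataFrame(rows, columns=["t_cross", "x_cross"])
    return SyntheticSession(scfg, bats, raw, events, duration, t_grid)


def _rate_scales(map2d: ModelMap2D, v: float) -> np.ndarray:
    """Per-position-row Hz conversion A = m0 * v / field_size.

    Rows outside any field (hotspot territory) use the mean field size so the
    hotspot also converts to a finite rate.
    """
    centers = bin_centers(map2d.pos_edges)
    sizes = [hi - lo for lo, hi, _ in map2d.fields]
    mean_size = float(np.mean(sizes)) if sizes else 10.0
    scale = np.full(centers.size, map2d.m0 * v / mean_size)
    for lo, hi, _ in map2d.fields:
        size = max(hi - lo, 1e-6)
        scale[(centers >= lo) & (centers < hi)] = map2d.m0 * v / size
    return scale


def instantaneous_rate(map2d: ModelMap2D, kin: dict[str, np.ndarray],
                       v_ref: float = 8.0,
                       direction: int | None = None) -> np.ndarray:
    """Hz firing rate along a session given a bat's ground-truth kinematics.

    During solo conditions (partner resting or |d| > distance range) the map is
    evaluated at its unmodulated positional profile.
    """
    scale = _rate_scales(map2d, v_ref)
    npos = map2d.rate_grid.shape[0]
    bw_p = map2d.pos_edges[1] - map2d.pos_edges[0]
    ip = np.clip(((kin["x"] - map2d.pos_edges[0]) / bw_p).astype(int), 0, npos - 1)

    d = -np.sign(kin["direction"]) * (kin["x_other"] - kin["x"])
    dmax = map2d.dist_edges[-1]
    paired = kin["other_flying"] & (np.abs(d) <= dmax) & (kin["direction"] != 0)

    rate = np.zeros(kin["t"].size)
    pos_prof = map2d.position_profile
    solo_mask = kin["flying"] & ~paired
    rate[solo_mask] = scale[ip[solo_mask]] * pos_prof[ip[solo_mask]]
    pm = kin["flying"] & paired
    rate[pm] = scale[ip[pm]] * map2d.lookup(d[pm], kin["x"][pm])
    if direction is not None:
        rate[kin["direction"] != direction] = 0.0
    if not np.all(np.isfinite(rate)):
        raise ValueError("non-finite instantaneous rate")
    return rate


def _poisson_times(t: np.ndarray, rate: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson sampling on a uniform grid (piecewise-constant rate)."""
    if t.size == 0:
        return np.array([])
    dt = t[1] - t[0] if t.size > 1 else 0.0
    counts = rng.poisson(rate * dt)
    reps = np.repeat(np.arange(t.size), counts)
    times = t[reps] + rng.uniform(0.0, dt, size=reps.size)
    return np.sort(times)


def simulate_spikes(map2d: ModelMap2D, session: SyntheticSession, bat: int, rng,
                    direction: int | None = None,
                    gain_windows: list[tuple[float, float, float]] | None = None
                    ) -> np.ndarray:
    """Spike timestamps of one model neuron across a session.

    ``gain_windows`` optionally scales the instantaneous rate by a factor
    inside given (t_start, t_end, gain) intervals — used to inject
    attention-dependent rate modulation on selected flights.
    """
    rng = as_rng(rng)
    kin = session.kinematics(bat)
    rate = instantaneous_rate(map2d, kin, v_ref=session.cfg.speed_mean,
                              direction=direction)
    if gain_windows:
        for t0, t1, g in gain_windows:
            rate[(kin["t"] >= t0) & (kin["t"] <= t1)] *= g
    return _poisson_times(kin["t"], rate, rng)


def coarse_hz_grids(map2d: ModelMap2D, v_ref: float = 8.0,
                    coarse_bin: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """(2D Hz map, position-only Hz map) on a coarse grid.

    Block-averages the model's 0.5 m grid onto ``coarse_bin`` bins after the
    A_f = m0 v / field_size conversion to Hz — the resolution of the measured
    2D cross-over rate maps.
    """
    scale = _rate_scales(map2d, v_ref)
    hz2d = map2d.rate_grid * scale[:, None]
    hz_pos = map2d.position_profile * scale
    f = int(round(coarse_bin / (map2d.pos_edges[1] - map2d.pos_edges[0])))
    rows = (hz2d.shape[0] // f) * f
    cols = (hz2d.shape[1] // f) * f
    coarse2d = hz2d[:rows, :cols].reshape(rows // f, f, cols // f, f).mean(axis=(1, 3))
    coarse_pos = hz_pos[:rows].reshape(rows // f, f).mean(axis=1)
    return coarse2d, coarse_pos


def sample_rate_map(rate_hz: np.ndarray, occupancy_s: float | np.ndarray,
                    rng, sigma_bins: float = 1.5) -> np.ndarray:
    """Poisson-sample spike counts from a Hz grid and re-estimate a smoothed
    rate map, emulating the measurement noise of session rate maps."""
    from ..utils import smooth_valid_2d

    rng = as_rng(rng)
    occ = np.broadcast_to(np.asarray(occupancy_s, dtype=float), rate_hz.shape)
    counts = rng.poisson(rate_hz * occ).astype(float)
    valid = np.ones(rate_hz.shape, dtype=bool)
    sm_c = smooth_valid_2d(counts, valid, sigma_bins)
    sm_o = smooth_valid_2d(occ.copy(), valid, sigma_bins)
    return sm_c / sm_o


def click_rate_factor(d: np.ndarray, scfg: SessionConfig) -> np.ndarray:
    """Attention-driven multiplier of click rate vs signed interbat distance.

    Ramps from 1 at ``click_rise_onset`` to ``click_rise_factor`` over
    ``click_ramp_len`` metres, plateaus up to the cross-over (d = 0), and
    resets to 1 once the partner has been passed.
    """
    onset = scfg.click_rise_onset
    ramp_end = onset + scfg.click_ramp_len
    factor = np.ones_like(d, dtype=float)
    in_ramp = (d >= onset) & (d < ramp_end)
    factor[in_ramp] = 1.0 + (scfg.click_rise_factor - 1.0) * (
        (d[in_ramp] - onset) / scfg.click_ramp_len)
    factor[(d >= ramp_end) & (d <= 0.0)] = scfg.click_rise_factor
    return factor


def simulate_clicks(session: SyntheticSession, rng,
                    bat: int | None = None) -> dict[int, np.ndarray]:
    """Paired echolocation clicks per bat as a rate-modulated point process."""
    rng = as_rng(rng)
    scfg = session.cfg
    out = {}
    for b in ([bat] if bat is not None else [0, 1]):
        kin = session.kinematics(b)
        d = -np.sign(kin["direction"]) * (kin["x_other"] - kin["x"])
        factor = np.ones_like(d)
        paired = kin["other_flying"] & (kin["direction"] != 0)
        factor[paired] = click_rate_factor(d[paired], scfg)
        rate = np.where(kin["flying"], scfg.click_base_rate * factor, 0.0)
        pair_times = _poisson_times(kin["t"], rate / 2.0, rng)
        times = np.sort(np.concatenate([pair_times,
                                        pair_times + scfg.click_pair_gap]))
        out[b] = times
    return out
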