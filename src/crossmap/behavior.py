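"""Trajectory preprocessing and segmentation into behavioural modes.

Sign convention for the interbat distance, used throughout the package:
``d = -sign(vx_self) * (x_other - x_self)`` — negative while the bats approach
each other and positive after they have passed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .utils import contiguous_runs

TARGET_RATE = 100.0          # Hz after preprocessing
MAX_SPEED = 20.0             # m/s, outlier threshold
MAX_LATERAL_DEV = 2.0        # m, perpendicular outlier threshold
MAX_GAP = 0.5                # s, longest gap bridged by interpolation
FLIGHT_SPEED_MIN = 2.0       # m/s
BALL_MARGIN = 3.0            # m, exclusion around landing balls
UTURN_TRIM = 3.0             # m trimmed on each side of a mid-tunnel U-turn
SOLO_DIST = 40.0             # |d| beyond which the partner is ignored
SOLO_MIN_DUR = 2.0           # s
CROSS_WINDOW = 40.0          # m, +-window around a cross-over
CROSS_BALL_MARGIN = 8.0      # m, valid cross-overs must be this far from balls
CROSS_MIN_OPPOSITE = 5.0     # m of opposite-direction flight on each side
TRACK_DIST = 20.0            # m, tracking threshold


@dataclass
class Trajectory:
    """Uniform 100 Hz preprocessed trajectory of one bat."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    valid: np.ndarray

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def sample_at(self, times: np.ndarray, field: str = "x") -> np.ndarray:
        return np.interp(times, self.t, getattr(self, field))


@dataclass
class CrossoverFlight:
    """The +-40 m distance window around one cross-over event."""

    t_cross: float
    x_cross: float
    direction: int
    t: np.ndarray = dfield(repr=False, default=None)
    x: np.ndarray = dfield(repr=False, default=None)
    d: np.ndarray = dfield(repr=False, default=None)
    valid: bool = True
    invalid_reason: str = ""

    def d_of_spikes(self, spike_times: np.ndarray) -> np.ndarray:
        return np.interp(spike_times, self.t, self.d)

    def x_of_spikes(self, spike_times: np.ndarray) -> np.ndarray:
        return np.interp(spike_times, self.t, self.x)


def preprocess_trajectory(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                          max_gap: float = MAX_GAP) -> Trajectory:
    """Clean raw tag samples and resample to a uniform 100 Hz grid.

    Outliers (lateral deviation > 2 m or implied speed > 20 m/s) are dropped,
    gaps up to ``max_gap`` seconds are linearly interpolated, and longer gaps
    are left invalid (segments are split rather than bridged).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(t) & np.isfinite(x) & np.isfinite(y)
    keep &= np.abs(y) <= MAX_LATERAL_DEV
    tv, xv, yv = t[keep], x[keep], y[keep]
    if tv.size >= 2:
        # implied speed between consecutive retained samples
        while True:
            dt = np.diff(tv)
            with np.errstate(divide="ignore", invalid="ignore"):
                sp = np.abs(np.diff(xv)) / np.where(dt > 0, dt, np.inf)
            bad = np.flatnonzero(sp > MAX_SPEED)
            if bad.size == 0:
                break
            drop = np.zeros(tv.size, dtype=bool)
            drop[bad + 1] = True
            tv, xv, yv = tv[~drop], xv[~drop], yv[~drop]
    if tv.size < 2:
        empty = np.array([])
        return Trajectory(empty, empty, empty, empty, empty,
                          np.array([], dtype=bool))

    tg = np.arange(tv[0], tv[-1] + 0.5 / TARGET_RATE, 1.0 / TARGET_RATE)
    xg = np.interp(tg, tv, xv)
    yg = np.interp(tg, tv, yv)
    valid = np.ones(tg.size, dtype=bool)
    gaps = np.diff(tv)
    for i in np.flatnonzero(gaps > max_gap):
        valid[(tg > tv[i]) & (tg < tv[i + 1])] = False
    vx = np.gradient(xg, tg)
    vy = np.gradient(yg, tg)
    return Trajectory(tg, xg, yg, vx, vy, valid)


def _uturn_mask(traj: Trajectory, ball_low: float, ball_high: float,
                hysteresis: float = 0.5) -> np.ndarray:
    """Samples within UTURN_TRIM metres (along the path) of a mid-tunnel U-turn.

    A U-turn is a sign change of vx away from the balls; hysteresis on vx
    suppresses jitter around zero.
    """
    sign = np.zeros(traj.t.size, dtype=np.int8)
    cur = 0
    for i, v in enumerate(traj.vx):
        if v > hysteresis:
            cur = 1
        elif v < -hysteresis:
            cur = -1
        sign[i] = cur
    flips = np.flatnonzero((sign[:-1] * sign[1:]) == -1) + 1
    mask = np.zeros(traj.t.size, dtype=bool)
    for i in flips:
        x0 = traj.x[i]
        if x0 <= ball_low + BALL_MARGIN or x0 >= ball_high - BALL_MARGIN:
            continue
        mask |= np.abs(traj.x - x0) < UTURN_TRIM
    return mask


def extract_flights(traj: Trajectory, ball_low: float = 5.0,
                    ball_high: float = 130.0) -> pd.DataFrame:
    """Flight epochs: speed > 2 m/s, > 3 m from both balls, U-turns trimmed.

    Returns one row per segment: t_start, t_end, direction, i_start, i_stop.
    """
    if traj.t.size == 0:
        return pd.DataFrame(columns=["t_start", "t_end", "direction",
                                     "i_start", "i_stop"])
    ok = traj.valid & (traj.speed > FLIGHT_SPEED_MIN)
    ok &= (traj.x > ball_low + BALL_MARGIN) & (traj.x < ball_high - BALL_MARGIN)
    ok &= ~_uturn_mask(traj, ball_low, ball_high)
    rows = []
    for i0, i1 in contiguous_runs(ok):
        if i1 - i0 < 5:
            continue
        direction = int(np.sign(np.mean(traj.vx[i0:i1])))
        if direction == 0:
            continue
        rows.append({"t_start": traj.t[i0], "t_end": traj.t[i1 - 1],
                     "direction": direction, "i_start": i0, "i_stop": i1})
    return pd.DataFrame(rows, columns=["t_start", "t_end", "direction",
                                       "i_start", "i_stop"])


def signed_distance(traj_self: Trajectory, traj_other: Trajectory) -> np.ndarray:
    """d(t) on the self trajectory's grid; negative while approaching."""
    x_other = np.interp(traj_self.t, traj_other.t, traj_other.x)
    return -np.sign(traj_self.vx) * (x_other - traj_self.x)


@dataclass
class FlightTable:
    """Per-bat mode segments plus the cross-over flights of the recorded bat."""

    segments: pd.DataFrame          # bat, mode, t_start, t_end, direction, flags
    crossovers: list[CrossoverFlight]

    def solo_segments(self, bat: int = 0) -> pd.DataFrame:
        s = self.segments
        return s[(s.bat == bat) & (s["mode"] == "solo")]

    def valid_crossovers(self) -> list[CrossoverFlight]:
        return [c for c in self.crossovers if c.valid]


def segment_modes(traj_self: Trajectory, traj_other: Trajectory,
                  flights_self: pd.DataFrame, flights_other: pd.DataFrame,
                  ball_low: float = 5.0, ball_high: float = 130.0,
                  bat: int = 0) -> FlightTable:
    """Label the recorded bat's flight time as solo / cross-over / tracking.

    Precedence on overlap: cross-over > tracking > solo.
    """
    t = traj_self.t
    x_other = np.interp(t, traj_other.t, traj_other.x)
    other_flying = np.interp(t, traj_other.t,
                             (traj_other.speed > FLIGHT_SPEED_MIN).astype(float)) > 0.5
    vx_other = np.interp(t, traj_other.t, traj_other.vx)

    in_flight = np.zeros(t.size, dtype=bool)
    for _, f in flights_self.iterrows():
        in_flight[int(f.i_start):int(f.i_stop)] = True

    d = -np.sign(traj_self.vx) * (x_other - traj_self.x)
    same_dir = np.sign(traj_self.vx) == np.sign(vx_other)

    # cross-over events: raw separation changes sign while both fly opposite
    sep = x_other - traj_self.x
    opposite = in_flight & other_flying & ~same_dir
    zc = np.flatnonzero((np.sign(sep[:-1]) * np.sign(sep[1:]) < 0)
                        & opposite[:-1] & opposite[1:])

    crossovers: list[CrossoverFlight] = []
    cross_mask = np.zeros(t.size, dtype=bool)
    for i in zc:
        frac = sep[i] / (sep[i] - sep[i + 1])
        t_cross = t[i] + frac * (t[i + 1] - t[i])
        x_cross = float(np.interp(t_cross, t, traj_self.x))
        direction = int(np.sign(traj_self.vx[i]))
        # contiguous window around the event where |d| <= 40 and self in flight
        lo = i
        while lo > 0 and in_flight[lo - 1] and abs(d[lo - 1]) <= CROSS_WINDOW \
                and not same_dir[lo - 1]:
            lo -= 1
        hi = i + 1
        while hi < t.size - 1 and in_flight[hi + 1] and abs(d[hi + 1]) <= CROSS_WINDOW \
                and not same_dir[hi + 1]:
            hi += 1
        sl = slice(lo, hi + 1)
        co = CrossoverFlight(t_cross=float(t_cross), x_cross=x_cross,
                             direction=direction, t=t[sl].copy(),
                             x=traj_self.x[sl].copy(), d=d[sl].copy())
        reasons = []
        if (x_cross < ball_low + CROSS_BALL_MARGIN
                or x_cross > ball_high - CROSS_BALL_MARGIN):
            reasons.append("near_ball")
        before = opposite[lo:i + 1]
        after = opposite[i + 1:hi + 1]
        span_before = np.ptp(traj_self.x[lo:i + 1][before]) if before.any() else 0.0
        span_after = np.ptp(traj_self.x[i + 1:hi + 1][after]) if after.any() else 0.0
        if span_before < CROSS_MIN_OPPOSITE or span_after < CROSS_MIN_OPPOSITE:
            reasons.append("short_opposite")
        co.valid = not reasons
        co.invalid_reason = ",".join(reasons)
        crossovers.append(co)
        cross_mask[sl] = True

    tracking_mask = (in_flight & other_flying & same_dir
                     & (np.abs(d) < TRACK_DIST) & ~cross_mask)
    solo_mask = (in_flight & (~other_flying | (np.abs(d) > SOLO_DIST))
                 & ~cross_mask & ~tracking_mask)

    rows = []
    for mode, mask in (("crossover", cross_mask), ("tracking", tracking_mask),
                       ("solo", solo_mask)):
        for i0, i1 in contiguous_runs(mask & in_flight):
            dur = t[i1 - 1] - t[i0]
            if mode == "solo" and dur < SOLO_MIN_DUR:
                continue
            direction = int(np.sign(np.mean(traj_self.vx[i0:i1])))
            rows.append({"bat": bat, "mode": mode, "t_start": t[i0],
                         "t_end": t[i1 - 1], "direction": direction,
                         "i_start": i0, "i_stop": i1})
    segments = pd.DataFrame(rows, columns=["bat", "mode", "t_start", "t_end",
                                           "direction", "i_start", "i_stop"])
    return FlightTable(segments=segments, crossovers=crossovers)


def solo_flight_records(traj: Trajectory, table: FlightTable,
                        bat: int = 0) -> list[dict]:
    """Per-solo-segment records (t, x arrays) used by the projection shuffle."""
    out = []
    for _, seg in table.solo_segments(bat).iterrows():
        sl = slice(int(seg.i_start), int(seg.i_stop))
        out.append({"t": traj.t[sl], "x": traj.x[sl],
                    "direction": int(seg.direction),
                    "t_start": float(seg.t_start), "t_end": float(seg.t_end)})
    return out
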