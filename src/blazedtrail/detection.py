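"""Speed-signature detection of scent-marking events and bout statistics.

An ant deposits a scent mark in a sharp stop-and-go episode lasting
about 0.2 s: the speed profile shows a local minimum below 3.5 cm/s
flanked by deceleration and acceleration whose magnitude exceeds
30 cm/s^2 within a 0.25 s window.  The detector implements this
automatic screen; thresholds are configuration-exposed.  Consecutive
marks by one ant form a bout whose length is the distance from the load
to the furthest mark in the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Trajectory",
    "DetectorConfig",
    "MarkEvent",
    "Bout",
    "speed_profile",
    "detect_marks",
    "segment_bouts",
    "median_ci_binomial",
    "extreme_bout_probability",
]


@dataclass
class Trajectory:
    """Timed positions of one ant or load: t in s, x/y in cm, uniformly
    sampled at ``frame_rate`` Hz."""

    id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.any(np.abs(dt - 1.0 / self.frame_rate) > 0.2 / self.frame_rate):
                raise ValueError("sampling must be uniform at frame_rate")

    def position_at(self, time: float) -> np.ndarray:
        return np.array(
            [np.interp(time, self.t, self.x), np.interp(time, self.t, self.y)]
        )


@dataclass
class DetectorConfig:
    """Thresholds of the marking-event screen.

    window_s : screening window (s), centered on each speed minimum.
    v_min    : the local speed minimum must fall below this (cm/s).
    a_min    : |deceleration| before and |acceleration| after the minimum
               must exceed this within the window (cm/s^2).
    smoothing_frames : moving-average width applied to positions before
               differentiation (1 = no smoothing).
    """

    window_s: float = 0.25
    v_min: float = 3.5
    a_min: float = 30.0
    smoothing_frames: int = 3

    def __post_init__(self) -> None:
        if min(self.window_s, self.v_min, self.a_min, self.smoothing_frames) <= 0:
            raise ValueError("all detector parameters must be positive")


@dataclass
class MarkEvent:
    ant_id: str
    t: float
    x: float
    y: float


@dataclass
class Bout:
    """Consecutive marking sequence of one ant.

    start_distance_cm : load-to-first-mark distance at the first event.
    bout_length_cm    : max over events of the load-to-mark distance,
                        each measured at that event's time.
    """

    ant_id: str
    events: list[MarkEvent]
    start_distance_cm: float
    bout_length_cm: float


def _moving_average(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(values)]
    return out


def _derivative(values: np.ndarray, dt: float) -> np.ndarray:
    """Central differences, one-sided at the endpoints."""
    out = np.empty_like(values)
    out[1:-1] = (values[2:] - values[:-2]) / (2 * dt)
    out[0] = (values[1] - values[0]) / dt
    out[-1] = (values[-1] - values[-2]) / dt
    return out


def speed_profile(
    traj: Trajectory, cfg: DetectorConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample speed (cm/s) and acceleration (cm/s^2).

    Positions are optionally moving-average smoothed; speed comes from
    central differences of position, acceleration from the derivative of
    speed.
    """
    cfg = cfg or DetectorConfig()
    if len(traj.t) < 3:
        raise ValueError("speed_profile needs at least 3 samples")
    dt = 1.0 / traj.frame_rate
    x = _moving_average(traj.x, cfg.smoothing_frames)
    y = _moving_average(traj.y, cfg.smoothing_frames)
    vx = _derivative(x, dt)
    vy = _derivative(y, dt)
    speed = np.hypot(vx, vy)
    accel = _derivative(speed, dt)
    return speed, accel


def detect_marks(
    traj: Trajectory, cfg: DetectorConfig | None = None
) -> list[MarkEvent]:
    """Marking events from the stop-and-go speed signature.

    A candidate is a local speed minimum below ``v_min`` whose centered
    ``window_s`` neighbourhood contains deceleration of magnitude above
    ``a_min`` before the minimum and acceleration above ``a_min`` after
    it.  Candidates closer together than the window are merged, keeping
    the slowest; the event position is the trajectory position at the
    minimum.
    """
    cfg = cfg or DetectorConfig()
    speed, accel = speed_profile(traj, cfg)
    half = max(1, int(round(cfg.window_s / 2 * traj.frame_rate)))
    n = len(speed)
    candidates = []
    for i in range(1, n - 1):
        if speed[i] >= cfg.v_min:
            continue
        if not (speed[i] <= speed[i - 1] and speed[i] <= speed[i + 1]):
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        decel_before = -accel[lo : i + 1].min() if i > lo else 0.0
        accel_after = accel[i:hi].max() if hi > i else 0.0
        if decel_before > cfg.a_min and accel_after > cfg.a_min:
            candidates.append(i)
    # deduplicate: within one window keep the deepest minimum
    events: list[int] = []
    for i in sorted(candidates, key=lambda j: speed[j]):
        if all(abs(i - j) > 2 * half for j in events):
            events.append(i)
    events.sort()
    return [
        MarkEvent(ant_id=traj.id, t=float(traj.t[i]), x=float(traj.x[i]), y=float(traj.y[i]))
        for i in events
    ]


def segment_bouts(
    events: list[MarkEvent],
    load_track: Trajectory,
    max_gap_s: float = 2.0,
) -> list[Bout]:
    """Group each ant's marks into bouts (inter-mark gap <= max_gap_s)
    and measure the bout geometry against the load track.

    Events of different ants are never merged; every event belongs to
    exactly one bout.
    """
    bouts: list[Bout] = []
    by_ant: dict[str, list[MarkEvent]] = {}
    for ev in events:
        by_ant.setdefault(ev.ant_id, []).append(ev)
    for ant_id, evs in by_ant.items():
        evs = sorted(evs, key=lambda e: e.t)
        groups: list[list[MarkEvent]] = [[evs[0]]]
        for ev in evs[1:]:
            if ev.t - groups[-1][-1].t <= max_gap_s:
                groups[-1].append(ev)
            else:
                groups.append([ev])
        for grp in groups:
            dists = []
            for ev in grp:
                load = load_track.position_at(ev.t)
                dists.append(float(np.hypot(ev.x - load[0], ev.y - load[1])))
            bouts.append(
                Bout(
                    ant_id=ant_id,
                    events=grp,
                    start_distance_cm=dists[0],
                    bout_length_cm=max(dists),
                )
            )
    return bouts


def median_ci_binomial(values, conf: float = 0.95) -> tuple[float, float]:
    """Conservative order-statistic confidence interval for the median.

    With n sorted values x_(1..n), the number of observations below the
    true median is Binomial(n, 1/2); picking the largest symmetric ranks
    (l, n+1-l) with cdf(l-1) <= (1-conf)/2 gives coverage >= conf.  When
    even the full range cannot reach the requested confidence (small n),
    (x_(1), x_(n)) is returned — the widest available interval.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("median_ci_binomial needs at least one value")
    alpha = 1.0 - conf
    ks = np.arange(1, n // 2 + 2)
    ok = stats.binom.cdf(ks - 1, n, 0.5) <= alpha / 2
    l = int(ks[ok].max()) if ok.any() else 1
    u = n + 1 - l
    if u < l:  # n == 1
        u = l
    return float(x[l - 1]), float(x[u - 1])


def extreme_bout_probability(
    n_extreme: int, n_total: int, k: int
) -> tuple[float, float]:
    """Empirical tail fraction p = n_extreme / n_total and p**k, the
    probability of k independent draws all landing in the tail."""
    if not 0 <= n_extreme <= n_total or n_total < 1 or k < 1:
        raise ValueError("require 0 <= n_extreme <= n_total, n_total >= 1, k >= 1")
    p = n_extreme / n_total
    return p, p**k
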