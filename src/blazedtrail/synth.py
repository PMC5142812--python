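"""Synthetic trajectories, marks, bouts and speed profiles.

Generates data with the statistical structure of cooperative-transport
recordings — a load track with ~10 cm persistence length, collective
marking at ~1.4 marks/s biased toward the nest, bouts starting ~3 cm
from the load with a ~9.5 cm median length, and single-ant speed
profiles containing ~0.2 s stop-and-go marking dips — so that every
analysis module can be exercised and validated without field data.
The distributional families (wrapped-Gaussian turning, von Mises mark
directions, log-normal bout lengths) are generator choices: real
recordings fix only the summary statistics these defaults reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import MarkEvent, Trajectory
from .metrics import fit_scaling

__all__ = [
    "SynthSpec",
    "generate_load_track",
    "measure_persistence_length",
    "generate_marks",
    "generate_marking_speed_profile",
    "generate_bout_lengths",
]


@dataclass
class SynthSpec:
    """Study conditions for the generator.

    Defaults reproduce the field-scale summary statistics: 10 cm
    persistence length, 1.4 marks/s, bout start 3.1 +/- 1.9 cm from the
    load, 9.5 cm median bout length, 0.2 s marking dips.  The bout-length
    log-SD of 2.06 places 2.2% of bouts at or beyond 6 m, matching the
    observed 16/735 extreme-tail fraction; the angular concentration
    kappa = 3.6 puts per-mark information at the ~1.4 bit scale of field
    marks.
    """

    duration_s: float = 600.0
    frame_rate: float = 50.0
    load_speed_cm_s: float = 1.5
    persistence_length_cm: float = 10.0
    mark_rate_hz: float = 1.4
    nest_direction_deg: float = 0.0
    angular_concentration: float = 3.6
    bout_start_mean_cm: float = 3.1
    bout_start_sd_cm: float = 1.9
    bout_length_median_cm: float = 9.5
    bout_length_log_sd: float = 2.06
    dip_depth_cm_s: float = 4.5
    dip_width_s: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            self.duration_s, self.frame_rate, self.load_speed_cm_s,
            self.persistence_length_cm, self.mark_rate_hz,
            self.bout_start_mean_cm, self.bout_length_median_cm,
            self.dip_depth_cm_s, self.dip_width_s,
        )
        if min(positive) <= 0:
            raise ValueError("all rates and lengths must be positive")
        if self.angular_concentration < 0:
            raise ValueError("angular_concentration must be >= 0")


def generate_load_track(spec: SynthSpec) -> Trajectory:
    """Correlated-direction walk at constant speed.

    Per-frame heading increments are Gaussian with variance
    2 * step / persistence_length, which makes the directional
    autocorrelation decay as exp(-s / persistence_length) in arc
    length s.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.duration_s * spec.frame_rate)
    ds = spec.load_speed_cm_s / spec.frame_rate
    sigma = np.sqrt(2.0 * ds / spec.persistence_length_cm)
    headings = np.cumsum(rng.normal(0.0, sigma, size=n))
    t = np.arange(n) / spec.frame_rate
    x = np.concatenate([[0.0], np.cumsum(ds * np.cos(headings))])[:n]
    y = np.concatenate([[0.0], np.cumsum(ds * np.sin(headings))])[:n]
    return Trajectory(id="load", t=t, x=x, y=y, frame_rate=spec.frame_rate)


def measure_persistence_length(traj: Trajectory, corr_floor: float = 0.3) -> float:
    """Empirical persistence length from the exponential decay of the
    directional autocorrelation versus arc length.

    Only the initial decay (correlation above ``corr_floor``, contiguous
    from lag one) enters the log-linear fit: on a single finite track the
    long-lag correlation estimates sit on a noise floor that would
    otherwise flatten the fitted slope.
    """
    dx, dy = np.diff(traj.x), np.diff(traj.y)
    steps = np.hypot(dx, dy)
    ds = float(steps.mean())
    headings = np.unwrap(np.arctan2(dy, dx))
    max_lag = max(3, len(headings) // 4)
    lags, corr = [], []
    for k in range(1, max_lag):
        c = float(np.mean(np.cos(headings[k:] - headings[:-k])))
        if c <= corr_floor:
            break
        lags.append(k)
        corr.append(c)
    if len(lags) < 3:
        raise ValueError("track too short or too erratic to fit a persistence length")
    fit = fit_scaling(np.asarray(lags) * ds, np.asarray(corr), model="exponential")
    return -1.0 / fit.coefficients["rate"]


def generate_marks(
    spec: SynthSpec, load_track: Trajectory
) -> tuple[list[MarkEvent], np.ndarray]:
    """Homogeneous-rate marking events around the moving load.

    Event times form a Poisson process at ``mark_rate_hz``; each mark is
    offset from the load position by a distance ~ N(bout_start_mean,
    bout_start_sd) (clipped positive) in an absolute direction drawn von
    Mises around ``nest_direction_deg`` with concentration kappa.
    Returns the events and the ground-truth angular deviations (degrees,
    relative to the nest direction) for estimator validation.
    """
    rng = np.random.default_rng(spec.seed + 1)
    duration = float(load_track.t[-1] - load_track.t[0])
    n = rng.poisson(spec.mark_rate_hz * duration)
    times = np.sort(rng.uniform(load_track.t[0], load_track.t[-1], size=n))
    if spec.angular_concentration > 0:
        dev = rng.vonmises(0.0, spec.angular_concentration, size=n)
    else:
        dev = rng.uniform(-np.pi, np.pi, size=n)
    direction = np.radians(spec.nest_direction_deg) + dev
    radius = np.clip(
        rng.normal(spec.bout_start_mean_cm, spec.bout_start_sd_cm, size=n),
        0.1,
        None,
    )
    marks = []
    for i in range(n):
        load = load_track.position_at(times[i])
        marks.append(
            MarkEvent(
                ant_id=f"marker_{i}",
                t=float(times[i]),
                x=float(load[0] + radius[i] * np.cos(direction[i])),
                y=float(load[1] + radius[i] * np.sin(direction[i])),
            )
        )
    return marks, np.degrees(dev)


def generate_marking_speed_profile(
    spec: SynthSpec,
    n_events: int,
    baseline_speed: float = 5.0,
    noise_sd: float = 0.1,
    spacing_s: float = 1.5,
) -> tuple[Trajectory, np.ndarray]:
    """Single-ant speed profile with planted stop-and-go marking dips.

    The ant cruises at ``baseline_speed`` with additive Gaussian speed
    noise; each dip drops the speed by ``dip_depth_cm_s`` (floored at
    0.2 cm/s) and recovers within ``dip_width_s``, the sharp V shape of
    a marking episode.  Dips are spaced ``spacing_s`` apart (>= 1 s).
    Returns the trajectory and the ground-truth dip times.
    """
    if spacing_s < 1.0:
        raise ValueError("dips must be separated by at least 1 s")
    rng = np.random.default_rng(spec.seed + 2)
    duration = spacing_s * (n_events + 1)
    n = int(duration * spec.frame_rate)
    t = np.arange(n) / spec.frame_rate
    speed = baseline_speed + rng.normal(0.0, noise_sd, size=n)
    event_times = spacing_s * (np.arange(n_events) + 1.0)
    half = spec.dip_width_s / 2.0
    floor = 0.2
    for t0 in event_times:
        shape = np.clip(1.0 - np.abs(t - t0) / half, 0.0, None)
        dip = np.minimum(spec.dip_depth_cm_s * shape, baseline_speed - floor)
        speed -= dip
    speed = np.clip(speed, floor * 0.5, None)
    x = np.concatenate([[0.0], np.cumsum(speed[:-1] / spec.frame_rate)])
    y = np.zeros(n)
    traj = Trajectory(id="ant_0", t=t, x=x, y=y, frame_rate=spec.frame_rate)
    return traj, event_times


def generate_bout_lengths(spec: SynthSpec, n: int) -> np.ndarray:
    """Right-skewed marking-bout lengths (cm): log-normal with median
    ``bout_length_median_cm`` and log-SD ``bout_length_log_sd``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed + 3)
    mu = np.log(spec.bout_length_median_cm)
    if spec.bout_length_log_sd == 0:
        return np.full(n, spec.bout_length_median_cm)
    return rng.lognormal(mean=mu, sigma=spec.bout_length_log_sd, size=n)
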