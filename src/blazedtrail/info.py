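"""Angular information content of scent marks.

Each scent mark, seen from the moving load, is a message about a
direction: the angle between a reference direction (load-to-nest, or the
load's direction of motion just before/after the mark) and the
load-to-mark line.  Angles are binned into 36 bins of 10 degrees and the
plug-in Shannon entropy of the normalized histogram quantifies the
uncertainty of the message set.  Information is the entropy reduction
relative to a reference: the uniform 36-bin distribution (absolute
information per mark) or the before-mark histogram (information gained
by the load).  Bootstrap noise on the raw counts gives a standard
deviation for every information value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detection import MarkEvent, Trajectory

__all__ = [
    "N_BINS",
    "AngleHistogram",
    "InfoEstimate",
    "bin_angles",
    "shannon_entropy",
    "info_absolute",
    "info_load",
    "mark_angles",
    "bootstrap_sd",
    "precision_from_bits",
]

logger = logging.getLogger(__name__)

N_BINS = 36
BIN_EDGES = np.linspace(-180.0, 180.0, N_BINS + 1)


@dataclass
class AngleHistogram:
    """36-bin angular histogram over [-180, 180) degrees, left-closed."""

    counts: np.ndarray
    n: float

    def probabilities(self) -> np.ndarray:
        if self.n <= 0:
            raise ValueError("histogram is empty")
        return self.counts / self.counts.sum()


@dataclass
class InfoEstimate:
    bits: float
    sd: float
    n: int
    kind: str  # "absolute" or "load"


def _wrap_deg(angles) -> np.ndarray:
    """Reduce angles mod 360 into [-180, 180); +180 maps to -180."""
    a = np.asarray(angles, dtype=float)
    return (a + 180.0) % 360.0 - 180.0


def bin_angles(angles_deg) -> AngleHistogram:
    a = _wrap_deg(angles_deg)
    if a.size == 0:
        raise ValueError("bin_angles needs at least one angle")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    counts, _ = np.histogram(a, bins=BIN_EDGES)
    return AngleHistogram(counts=counts.astype(float), n=float(a.size))


def shannon_entropy(h: AngleHistogram) -> float:
    """Plug-in entropy of the normalized histogram in bits (0 log 0 = 0)."""
    p = h.probabilities()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def info_absolute(
    h: AngleHistogram, n_boot: int = 0, seed: int = 0
) -> InfoEstimate:
    """Information per mark relative to the no-message (uniform) case:
    log2(36) - H.  With ``n_boot`` > 0 the bootstrap SD is attached."""
    bits = float(np.log2(N_BINS) - shannon_entropy(h))
    sd = bootstrap_sd(h, n_boot=n_boot, seed=seed) if n_boot else 0.0
    return InfoEstimate(bits=bits, sd=sd, n=int(h.n), kind="absolute")


def info_load(
    before: AngleHistogram,
    after: AngleHistogram,
    n_boot: int = 0,
    seed: int = 0,
) -> InfoEstimate:
    """Information gained by the load from a mark: H(before) - H(after).

    The value is signed: a wider after-distribution yields negative bits.
    The SD combines independent bootstraps of the two histograms in
    quadrature.
    """
    bits = float(shannon_entropy(before) - shannon_entropy(after))
    if n_boot:
        sd_b = bootstrap_sd(before, n_boot=n_boot, seed=seed)
        sd_a = bootstrap_sd(after, n_boot=n_boot, seed=seed + 1)
        sd = float(np.hypot(sd_b, sd_a))
    else:
        sd = 0.0
    return InfoEstimate(
        bits=bits, sd=sd, n=int(min(before.n, after.n)), kind="load"
    )


def _signed_angle_deg(ref: np.ndarray, vec: np.ndarray) -> float:
    """Angle from ref to vec, counterclockwise positive, in (-180, 180]."""
    cross = ref[0] * vec[1] - ref[1] * vec[0]
    dot = ref[0] * vec[0] + ref[1] * vec[1]
    return float(np.degrees(np.arctan2(cross, dot)))


def mark_angles(
    load_track: Trajectory,
    nest_xy,
    marks: list[MarkEvent],
    frame: str = "nest",
    window_s: float = 2.0,
) -> np.ndarray:
    """Angle of each mark as seen from the load, in one of three frames.

    ``nest``   : reference is the load-to-nest line at marking time.
    ``before`` : reference is the load's direction of motion over the
                 ``window_s`` seconds preceding the mark (secant of the
                 track).
    ``after``  : same, over the window following the mark.

    Angles are signed, counterclockwise positive.  Marks whose time (with
    the window margin where needed) falls outside the track are skipped;
    the skip count is logged.
    """
    if frame not in ("nest", "before", "after"):
        raise ValueError(f"unknown frame {frame!r}")
    t = load_track.t
    nest = np.asarray(nest_xy, dtype=float)
    angles = []
    skipped = 0
    for mk in marks:
        t_lo = mk.t - window_s if frame == "before" else mk.t
        t_hi = mk.t + window_s if frame == "after" else mk.t
        if t_lo < t[0] or t_hi > t[-1]:
            skipped += 1
            continue
        load = np.array(
            [np.interp(mk.t, t, load_track.x), np.interp(mk.t, t, load_track.y)]
        )
        to_mark = np.array([mk.x, mk.y]) - load
        if frame == "nest":
            ref = nest - load
        else:
            ta, tb = (t_lo, mk.t) if frame == "before" else (mk.t, t_hi)
            pa = np.array(
                [np.interp(ta, t, load_track.x), np.interp(ta, t, load_track.y)]
            )
            pb = np.array(
                [np.interp(tb, t, load_track.x), np.interp(tb, t, load_track.y)]
            )
            ref = pb - pa
        angles.append(_signed_angle_deg(ref, to_mark))
    if skipped:
        logger.warning("mark_angles: skipped %d marks outside the track window", skipped)
    return np.asarray(angles, dtype=float)


def bootstrap_sd(
    h: AngleHistogram,
    n_boot: int = 10_000,
    seed: int = 0,
    noise_scale: float = 1.0,
) -> float:
    """Bootstrap SD of the histogram entropy (and hence of any information
    value that is an affine function of it).

    Each replicate perturbs every raw count q_i to q_i + beta_i*sqrt(q_i)
    with beta_i uniform on [-1, 1], clips at zero, renormalizes, and
    recomputes the entropy; the SD of the replicate entropies is
    returned.  sqrt(q_i) scaling ties the perturbation to the counting
    error, so well-populated bins contribute smaller relative noise.
    """
    if h.n <= 0:
        raise ValueError("histogram is empty")
    rng = np.random.default_rng(seed)
    q = h.counts
    beta = rng.uniform(-1.0, 1.0, size=(n_boot, q.size)) * noise_scale
    noisy = np.clip(q + beta * np.sqrt(q), 0.0, None)
    totals = noisy.sum(axis=1)
    p = noisy / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    entropies = -terms.sum(axis=1)
    return float(entropies.std(ddof=0))


def precision_from_bits(total_bits: float) -> float:
    """Angular accuracy implied by a bit budget: 360 / 2**bits degrees.

    Each bit halves the directional uncertainty starting from a full
    circle.  The unrounded value is returned; rounding is the caller's
    business.
    """
    if total_bits < 0:
        raise ValueError("total_bits must be non-negative")
    return 360.0 / 2.0**total_bits
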