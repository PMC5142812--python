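"""Stretch statistics and scaling-law fits for walk batches.

Stretch is the hop count of a walk divided by the shortest-path hop
distance between its endpoints; *effective stretch* is the mean over the
best 90% of runs in a scenario (the worst 10% are discarded, because the
raw expectation can be unbounded in adversarial advice settings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .environments import AdviceGraph
from .walker import WalkResult

__all__ = [
    "StretchSummary",
    "stretch",
    "effective_stretch",
    "summarize_stretches",
    "FitResult",
    "fit_scaling",
]


@dataclass
class StretchSummary:
    """Batch summary: all stretch values, the 10%-trimmed mean ("effective
    stretch"), the median, and censoring counts.  Censored runs enter as
    their lower-bound stretch (max_steps / shortest hops)."""

    stretches: np.ndarray
    effective_stretch: float
    median_stretch: float
    n_total: int
    n_censored: int
    trim_fraction: float = 0.10


def stretch(result: WalkResult, g: AdviceGraph) -> float:
    """Hops divided by shortest-path hops.

    For a censored run this is ``max_steps / shortest_hops`` — a lower
    bound on the true stretch; the censored flag lives on the result.
    """
    if result.source == g.target:
        raise ValueError("stretch is undefined for source == target")
    return result.hops / g.shortest_hops(result.source)


def effective_stretch(values, trim: float = 0.10) -> float:
    """Mean of the lowest ceil((1-trim)*n) values.

    The largest values are discarded first; with trim=0 this is the plain
    mean.  Ties at the cut are broken by keeping earlier entries (a stable
    sort), which never changes the mean but keeps the kept-set well
    defined.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("effective_stretch needs a non-empty list")
    if not 0.0 <= trim < 1.0:
        raise ValueError(f"trim must lie in [0, 1), got {trim}")
    keep = math.ceil((1.0 - trim) * values.size)
    kept = np.sort(values, kind="stable")[:keep]
    return float(kept.mean())


def summarize_stretches(
    hops: np.ndarray,
    reached: np.ndarray,
    shortest: np.ndarray,
    trim: float = 0.10,
) -> StretchSummary:
    """Stretch summary from batch arrays (censored runs use hops = cap)."""
    shortest = np.asarray(shortest, dtype=float)
    if np.any(shortest <= 0):
        raise ValueError("stretch is undefined for source == target")
    values = np.asarray(hops, dtype=float) / shortest
    return StretchSummary(
        stretches=values,
        effective_stretch=effective_stretch(values, trim),
        median_stretch=float(np.median(values)),
        n_total=int(values.size),
        n_censored=int(np.count_nonzero(~np.asarray(reached, dtype=bool))),
        trim_fraction=trim,
    )


@dataclass
class FitResult:
    model: str
    coefficients: dict[str, float]
    r_squared: float


def fit_scaling(xs, ys, model: str = "linear") -> FitResult:
    """Least-squares fit of y = a + b x (linear) or y = A e^{r x}
    (exponential, fit as linear least squares on log y).

    Returns the coefficients and the coefficient of determination; for
    the exponential model R^2 is measured on the log scale, matching how
    the fit is performed.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 3:
        raise ValueError("need at least 3 points to fit a scaling law")
    if model == "exponential":
        if np.any(ys <= 0):
            raise ValueError("exponential fit requires strictly positive y values")
        target = np.log(ys)
    elif model == "linear":
        target = ys
    else:
        raise ValueError(f"unknown model {model!r}")
    slope, intercept = np.polyfit(xs, target, 1)
    pred = slope * xs + intercept
    ss_res = float(np.sum((target - pred) ** 2))
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if model == "linear":
        coef = {"slope": float(slope), "intercept": float(intercept)}
    else:
        coef = {"rate": float(slope), "prefactor": float(np.exp(intercept))}
    return FitResult(model=model, coefficients=coef, r_squared=r2)
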