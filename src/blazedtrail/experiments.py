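"""Scripted simulation experiments: line first-passage sweeps, the grid
stretch heatmap and robustness curves, and the enclosed-obstacle escape
model.

Protocols follow the simulation design for Probabilistic Following:
line sweeps take the median first-passage time over many independent
advice configurations (one walk each, leftmost source to rightmost
target); grid scans pool walks over environments x uniformly drawn
sources and report effective stretch; the escape model is a half-line
whose advice all points back at the origin, so travel away from it is
movement against pheromonal advice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environments import (
    AdviceGraph,
    Topology,
    WrongModel,
    build_grid_environment,
    build_line_environment,
)
from .metrics import effective_stretch, summarize_stretches
from .walker import mean_fpt_exact, run_walks

__all__ = [
    "SweepSpec",
    "line_fpt_sweep",
    "grid_effective_stretch",
    "grid_stretch_scan",
    "normalized_stretch_curve",
    "build_escape_line",
    "escape_time_profile",
    "escape_rate_mapping",
]

_SEED_MASK = 0x7FFFFFFF


def _subseeds(seed: int, n: int) -> np.ndarray:
    return (np.random.SeedSequence(seed).generate_state(n) & _SEED_MASK).astype(int)


@dataclass
class SweepSpec:
    """Parameters of a simulation sweep.

    Default repetition counts are scaled so the full figure suite runs on
    one CPU in minutes (line: 1e4 configurations per cell; grid: 200
    environments x 20 sources); paper-scale counts are reachable by
    raising ``reps`` / ``n_envs`` / ``n_sources``.
    """

    topology: Topology = Topology.LINE
    sizes: tuple[int, ...] = (8, 16, 32, 64, 128)
    reliabilities: tuple[float, ...] = (1.0, 0.9)
    follow_probs: tuple[float, ...] = (0.8,)
    n_envs: int = 200
    n_sources: int = 20
    reps: int = 10_000
    wrong_model: WrongModel = WrongModel.UNIFORM_NEIGHBOR
    seed: int = 0
    max_steps: int = 1_000_000

    def __post_init__(self) -> None:
        for p in list(self.reliabilities) + list(self.follow_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not self.sizes:
            raise ValueError("sizes must be non-empty")


def line_fpt_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Median first-passage hops per (N, p, q) on the line.

    Each cell draws ``reps`` independent advice configurations and runs
    one walk per configuration from the leftmost node to the rightmost
    target.  Cells where more than half the walks were censored carry a
    ``censored_heavy`` flag — their median is a lower bound.
    """
    if spec.topology is not Topology.LINE:
        raise ValueError("line_fpt_sweep requires a line topology spec")
    rows = []
    cells = [
        (n, p, q)
        for n in spec.sizes
        for p in spec.reliabilities
        for q in spec.follow_probs
    ]
    seeds = _subseeds(spec.seed, 2 * len(cells))
    for k, (n, p, q) in enumerate(cells):
        env_seeds = _subseeds(seeds[2 * k], spec.reps)
        hops = np.empty(spec.reps, dtype=np.int64)
        reached = np.empty(spec.reps, dtype=bool)
        walk_seeds = _subseeds(seeds[2 * k + 1], spec.reps)
        for i in range(spec.reps):
            g = build_line_environment(n, p, spec.wrong_model, seed=env_seeds[i])
            h, r = run_walks(g, [0], q, spec.max_steps, base_seed=walk_seeds[i])
            hops[i], reached[i] = h[0], r[0]
        n_cens = int(np.count_nonzero(~reached))
        rows.append(
            {
                "N": n,
                "p": p,
                "q": q,
                "median_hops": float(np.median(hops)),
                "n": spec.reps,
                "n_censored": n_cens,
                "censored_heavy": n_cens > spec.reps / 2,
            }
        )
    return pd.DataFrame(rows)


def grid_effective_stretch(
    side: int,
    reliability: float,
    follow_prob: float,
    n_envs: int,
    n_sources: int,
    max_steps: int = 1_000_000,
    seed: int = 0,
    trim: float = 0.10,
) -> dict:
    """One grid scenario: effective stretch pooled over environments x
    uniformly drawn sources (source != target)."""
    seeds = _subseeds(seed, 3)
    env_seeds = _subseeds(seeds[0], n_envs)
    walk_seeds = _subseeds(seeds[1], n_envs)
    src_rng = np.random.default_rng(seeds[2])
    all_hops, all_reached, all_short = [], [], []
    for i in range(n_envs):
        g = build_grid_environment(side, reliability, seed=env_seeds[i])
        candidates = np.delete(np.arange(g.n_nodes), g.target)
        sources = src_rng.choice(candidates, size=n_sources, replace=True)
        hops, reached = run_walks(
            g, sources, follow_prob, max_steps, base_seed=walk_seeds[i]
        )
        all_hops.append(hops)
        all_reached.append(reached)
        all_short.append(g.shortest_hops_all()[sources])
    summary = summarize_stretches(
        np.concatenate(all_hops),
        np.concatenate(all_reached),
        np.concatenate(all_short),
        trim=trim,
    )
    return {
        "side": side,
        "p": reliability,
        "q": follow_prob,
        "effective_stretch": summary.effective_stretch,
        "median_stretch": summary.median_stretch,
        "n": summary.n_total,
        "n_censored": summary.n_censored,
    }


def grid_stretch_scan(spec: SweepSpec) -> pd.DataFrame:
    """Effective-stretch matrix over (p, q) on the grid (heatmap data)."""
    if spec.topology is not Topology.GRID:
        raise ValueError("grid_stretch_scan requires a grid topology spec")
    side = spec.sizes[0]
    cells = [(p, q) for p in spec.reliabilities for q in spec.follow_probs]
    seeds = _subseeds(spec.seed, len(cells))
    rows = [
        grid_effective_stretch(
            side, p, q, spec.n_envs, spec.n_sources, spec.max_steps, seed=seeds[k]
        )
        for k, (p, q) in enumerate(cells)
    ]
    return pd.DataFrame(rows)


def normalized_stretch_curve(
    spec: SweepSpec,
    reference_q: float = 0.8,
    q_scan_step: float = 0.1,
) -> pd.DataFrame:
    """Per-reliability ratio of effective stretch at the reference follow
    probability to the minimum over a q scan of [0, 1].

    A ratio near 1 means the fixed reference policy is (near-)optimal for
    that environment; the robustness claim is that the ratio stays small
    across the whole reliability range.
    """
    q_grid = np.round(np.arange(0.0, 1.0 + q_scan_step / 2, q_scan_step), 10)
    if not np.any(np.isclose(q_grid, reference_q)):
        raise ValueError("reference_q must lie on the scanned q grid")
    scan_spec = SweepSpec(
        topology=Topology.GRID,
        sizes=spec.sizes,
        reliabilities=spec.reliabilities,
        follow_probs=tuple(q_grid),
        n_envs=spec.n_envs,
        n_sources=spec.n_sources,
        seed=spec.seed,
        max_steps=spec.max_steps,
    )
    scan = grid_stretch_scan(scan_spec)
    rows = []
    for p, block in scan.groupby("p", sort=True):
        i_min = block["effective_stretch"].idxmin()
        s_min = float(block.loc[i_min, "effective_stretch"])
        ref = block[np.isclose(block["q"], reference_q)]
        s_ref = float(ref["effective_stretch"].iloc[0])
        rows.append(
            {
                "p": float(p),
                "stretch_ref": s_ref,
                "stretch_min": s_min,
                "q_opt": float(block.loc[i_min, "q"]),
                "ratio": s_ref / s_min,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# enclosed-obstacle escape model

def build_escape_line(distance: int) -> AdviceGraph:
    """Half-line 0..distance where every interior node's advice points
    back toward the origin (all marks lead to the blocked slit); the
    origin reflects (its only neighbor is outward) and the target is the
    node at ``distance``."""
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    n = distance + 1
    from .environments import _line_csr  # shared CSR builder

    indptr, indices = _line_csr(n)
    advice = np.arange(-1, n - 1, dtype=np.int64)  # v -> v-1
    advice[0] = 1  # single neighbor
    advice[n - 1] = -1  # target
    return AdviceGraph(
        topology=Topology.LINE,
        n_nodes=n,
        target=n - 1,
        indptr=indptr,
        indices=indices,
        advice=advice,
        reliability=0.0,
        wrong_model=WrongModel.FLIP,
        seed=0,
    )


def escape_time_profile(
    follow_prob: float,
    distances,
    mode: str = "exact",
    n_runs: int = 1000,
    max_steps: int = 10_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean first-passage hops from the origin to each distance on the
    all-advice-backward half-line.

    With follow probability q the per-step backward probability at an
    interior node is q + (1-q)/2, so escape times grow exponentially with
    distance at base (1+q)/(1-q).  ``exact`` solves the absorbing chain;
    ``simulate`` averages PF runs.  q = 1 never escapes: the mean is
    infinite and returned as ``inf``.
    """
    distances = [int(d) for d in distances]
    rows = []
    seeds = _subseeds(seed, len(distances))
    for k, d in enumerate(distances):
        g = build_escape_line(d)
        if follow_prob >= 1.0:
            rows.append({"distance": d, "mean_hops": np.inf, "mode": mode})
            continue
        if mode == "exact":
            mean = mean_fpt_exact(g, 0, follow_prob)
        elif mode == "simulate":
            hops, reached = run_walks(
                g, np.zeros(n_runs, dtype=int), follow_prob, max_steps,
                base_seed=seeds[k],
            )
            if not np.all(reached):
                raise RuntimeError(
                    f"{np.count_nonzero(~reached)} escape runs censored at "
                    f"distance {d}; raise max_steps"
                )
            mean = float(hops.mean())
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append({"distance": d, "mean_hops": mean, "mode": mode})
    return pd.DataFrame(rows)


def escape_rate_mapping(step_length_cm: float, follow_prob: float) -> dict:
    """Map the line kernel's parameters to observable rates.

    Under the half-line escape kernel an against-advice (outward) turn
    happens with per-step probability (1-q)/2, i.e. once per
    ``step_length / ((1-q)/2)`` centimetres when each hop spans one
    persistence length; consecutive-distance escape times grow by the
    factor (1+q)/(1-q) per step.  This is this package's explicit model
    of the consistency between reversal rate, persistence length and
    follow probability; field reversal rates also fold in collective
    effects the kernel does not capture, so the mapping is exposed with
    its parameters rather than fitted.
    """
    if step_length_cm <= 0:
        raise ValueError("step_length_cm must be positive")
    if not 0.0 <= follow_prob < 1.0:
        raise ValueError("follow_prob must lie in [0, 1)")
    q = follow_prob
    p_against = (1.0 - q) / 2.0
    return {
        "against_advice_turns_per_cm": p_against / step_length_cm,
        "exponential_base_per_step": (1.0 + q) / (1.0 - q),
    }
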