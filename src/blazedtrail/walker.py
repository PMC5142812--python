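"""The Probabilistic-Following (PF) walk and an exact first-passage oracle.

At each node the agent obeys the local advice with probability q and
otherwise steps to a uniformly random neighbor (which may coincide with
the advised one, so the effective follow probability at a node of degree
d is q + (1-q)/d).  The agent is memoryless: no visited set, no sense of
orientation.  The exact oracle solves the absorbing Markov chain of this
kernel for the expected number of hops to the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit

from .environments import AdviceGraph

__all__ = ["WalkConfig", "WalkResult", "pf_walk", "run_walks", "mean_fpt_exact"]

_SEED_MASK = 0x7FFFFFFF  # numba's np.random.seed wants a non-negative int32


@dataclass
class WalkConfig:
    """Parameters of one PF walk.

    follow_prob : probability q of obeying the advice at each step.
    max_steps   : censoring cap; a walk that has not reached the target
                  after this many hops is returned censored, never dropped.
    seed        : RNG seed for this walk.
    """

    follow_prob: float
    max_steps: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.follow_prob <= 1.0:
            raise ValueError(f"follow_prob must lie in [0, 1], got {self.follow_prob}")
        if self.max_steps < 1:
            raise ValueError(f"max_steps must be >= 1, got {self.max_steps}")


@dataclass
class WalkResult:
    source: int
    hops: int
    reached: bool
    censored: bool
    path: list[int] | None = None


@njit(cache=True)
def _walk_kernel(indptr, indices, advice, target, source, q, max_steps, seed):
    np.random.seed(seed)
    v = source
    hops = 0
    while v != target and hops < max_steps:
        if np.random.random() < q:
            v = advice[v]
        else:
            lo = indptr[v]
            deg = indptr[v + 1] - lo
            v = indices[lo + np.random.randint(0, deg)]
        hops += 1
    return hops, v == target


@njit(cache=True)
def _walk_kernel_path(indptr, indices, advice, target, source, q, max_steps, seed, path):
    np.random.seed(seed)
    v = source
    hops = 0
    path[0] = v
    while v != target and hops < max_steps:
        if np.random.random() < q:
            v = advice[v]
        else:
            lo = indptr[v]
            deg = indptr[v + 1] - lo
            v = indices[lo + np.random.randint(0, deg)]
        hops += 1
        path[hops] = v
    return hops, v == target


@njit(cache=True)
def _batch_kernel(indptr, indices, advice, target, sources, q, max_steps, seeds):
    n = sources.shape[0]
    hops_out = np.empty(n, dtype=np.int64)
    reached_out = np.empty(n, dtype=np.bool_)
    for i in range(n):
        h, r = _walk_kernel(
            indptr, indices, advice, target, sources[i], q, max_steps, seeds[i]
        )
        hops_out[i] = h
        reached_out[i] = r
    return hops_out, reached_out


def _derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """One independent RNG seed per walk index; reproducible and
    order-independent (walk i always gets the same stream)."""
    state = np.random.SeedSequence(base_seed).generate_state(n)
    return (state & _SEED_MASK).astype(np.int64)


def pf_walk(
    g: AdviceGraph, source: int, cfg: WalkConfig, keep_path: bool = False
) -> WalkResult:
    """Run one Probabilistic-Following walk from ``source``."""
    if not 0 <= source < g.n_nodes:
        raise ValueError(f"source {source} is not a node of the graph")
    seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] & _SEED_MASK)
    if keep_path:
        buf = np.empty(cfg.max_steps + 1, dtype=np.int64)
        hops, reached = _walk_kernel_path(
            g.indptr, g.indices, g.advice, g.target, source,
            cfg.follow_prob, cfg.max_steps, seed, buf,
        )
        path = buf[: hops + 1].tolist()
    else:
        hops, reached = _walk_kernel(
            g.indptr, g.indices, g.advice, g.target, source,
            cfg.follow_prob, cfg.max_steps, seed,
        )
        path = None
    return WalkResult(
        source=source,
        hops=int(hops),
        reached=bool(reached),
        censored=not bool(reached),
        path=path,
    )


def run_walks(
    g: AdviceGraph,
    sources: np.ndarray | list[int],
    follow_prob: float,
    max_steps: int = 1_000_000,
    base_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Batch of PF walks; returns (hops, reached) arrays.

    Walk i draws its RNG stream from (base_seed, i), so batches are
    reproducible and insensitive to execution order.
    """
    sources = np.asarray(sources, dtype=np.int64)
    seeds = _derive_seeds(base_seed, len(sources))
    return _batch_kernel(
        g.indptr, g.indices, g.advice, g.target, sources,
        float(follow_prob), int(max_steps), seeds,
    )


def _reachable_under_kernel(g: AdviceGraph, follow_prob: float) -> np.ndarray:
    """Nodes from which the target is reachable under the PF kernel.

    For q < 1 every adjacency edge has positive probability and lines and
    grids are connected, so everything is reachable.  At q = 1 only advice
    edges carry probability; reverse-BFS from the target along them.
    """
    if follow_prob < 1.0:
        return np.ones(g.n_nodes, dtype=bool)
    rev: dict[int, list[int]] = {}
    for v in range(g.n_nodes):
        if v != g.target:
            rev.setdefault(int(g.advice[v]), []).append(v)
    reach = np.zeros(g.n_nodes, dtype=bool)
    stack = [g.target]
    reach[g.target] = True
    while stack:
        u = stack.pop()
        for w in rev.get(u, ()):
            if not reach[w]:
                reach[w] = True
                stack.append(w)
    return reach


def mean_fpt_exact(
    g: AdviceGraph, source: int, follow_prob: float, node_cap: int = 10_000
) -> float:
    """Expected hops from ``source`` to the target under the PF kernel.

    Solves the absorbing-chain system (I - Q) t = 1 over the transient
    nodes.  Returns ``inf`` when the target is unreachable in the kernel
    (only possible at q = 1 when the advice pointers form a cycle that
    traps the source).
    """
    if not 0 <= source < g.n_nodes:
        raise ValueError(f"source {source} is not a node of the graph")
    if g.n_nodes > node_cap:
        raise ValueError(
            f"graph has {g.n_nodes} nodes, above the linear-solve cap {node_cap}"
        )
    if source == g.target:
        return 0.0
    q = float(follow_prob)
    reach = _reachable_under_kernel(g, q)
    if not reach[source]:
        return np.inf
    transient = np.flatnonzero(reach & (np.arange(g.n_nodes) != g.target))
    idx = -np.ones(g.n_nodes, dtype=np.int64)
    idx[transient] = np.arange(len(transient))
    rows, cols, vals = [], [], []
    for v in transient:
        i = idx[v]
        nb = g.neighbors(v)
        for u in nb:
            p_move = (1.0 - q) / len(nb)
            if u == g.advice[v]:
                p_move += q
            if u != g.target:
                if idx[u] < 0:
                    # positive-probability edge into a non-reachable node can
                    # only happen at q=1 toward a trapped component, which
                    # reachability already excludes
                    raise RuntimeError("transition into unreachable node")
                rows.append(i)
                cols.append(idx[u])
                vals.append(-p_move)
        rows.append(i)
        cols.append(i)
        vals.append(1.0)
    m = len(transient)
    A = sp.csc_matrix(
        (np.asarray(vals), (np.asarray(rows), np.asarray(cols))), shape=(m, m)
    )
    # diagonal entries were appended as +1 alongside the -p_move terms
    t = spla.spsolve(A, np.ones(m))
    if not np.all(np.isfinite(t)):
        raise FloatingPointError("singular absorbing-chain system")
    return float(t[idx[source]])
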