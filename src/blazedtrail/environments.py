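"""Line and grid environments with per-node directional advice.

The terrain an ant team navigates is discretized into a graph whose edge
length matches the motion's persistence length.  Each node carries one
*advice* pointer to a neighbor: with probability ``reliability`` (p) the
pointer lies on a shortest path to the target, otherwise it is wrong in a
way set by ``wrong_model``.  Advice is drawn once and frozen for the
lifetime of the environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "Topology",
    "WrongModel",
    "AdviceGraph",
    "correct_advice",
    "build_line_environment",
    "build_grid_environment",
    "advice_accuracy",
    "save_environment",
    "load_environment",
]


class Topology(str, Enum):
    LINE = "line"
    GRID = "grid"


class WrongModel(str, Enum):
    #: wrong advice is uniform over all neighbors (may coincide with the
    #: correct pointer)
    UNIFORM_NEIGHBOR = "uniform_neighbor"
    #: wrong advice is the neighbor away from the target (line only)
    FLIP = "flip"


@dataclass
class AdviceGraph:
    """A line or 4-neighbor grid with one advice pointer per node.

    Adjacency is stored in CSR form (``indptr``/``indices``) so the walk
    kernel can consume it directly; ``advice[target]`` is -1 (the target
    carries no advice).  Correct pointers always form a spanning tree
    rooted at the target, so pure advice-following from any node reaches
    the target in exactly shortest-path hops when reliability is 1.
    """

    topology: Topology
    n_nodes: int
    target: int
    indptr: np.ndarray
    indices: np.ndarray
    advice: np.ndarray
    reliability: float
    wrong_model: WrongModel
    seed: int
    side: int | None = None

    def neighbors(self, v: int) -> np.ndarray:
        return self.indices[self.indptr[v] : self.indptr[v + 1]]

    def degree(self, v: int) -> int:
        return int(self.indptr[v + 1] - self.indptr[v])

    @property
    def adjacency(self) -> dict[int, set[int]]:
        """Node -> neighbor set (convenience view; CSR is authoritative)."""
        return {v: set(self.neighbors(v).tolist()) for v in range(self.n_nodes)}

    def coords(self, v: int) -> tuple[int, int]:
        """(row, col) of a grid node; row-major 0-based ids."""
        if self.topology is not Topology.GRID:
            raise ValueError("coords are defined for grid environments only")
        assert self.side is not None
        return divmod(v, self.side)

    def node_id(self, row: int, col: int) -> int:
        if self.topology is not Topology.GRID:
            raise ValueError("node_id is defined for grid environments only")
        assert self.side is not None
        if not (0 <= row < self.side and 0 <= col < self.side):
            raise ValueError(f"({row}, {col}) outside {self.side}x{self.side} grid")
        return row * self.side + col

    def shortest_hops(self, v: int) -> int:
        """Hop distance from ``v`` to the target (line: |Δ|, grid: Manhattan)."""
        if self.topology is Topology.LINE:
            return abs(self.target - v)
        r, c = self.coords(v)
        tr, tc = self.coords(self.target)
        return abs(tr - r) + abs(tc - c)

    def shortest_hops_all(self) -> np.ndarray:
        """Vector of hop distances to the target for every node."""
        nodes = np.arange(self.n_nodes)
        if self.topology is Topology.LINE:
            return np.abs(self.target - nodes)
        rows, cols = np.divmod(nodes, self.side)
        tr, tc = self.coords(self.target)
        return np.abs(tr - rows) + np.abs(tc - cols)


def correct_advice(v: int, g: AdviceGraph) -> int:
    """Tree-parent of ``v``: the unique correct pointer toward the target.

    On the line this is the neighbor toward the target.  On the grid the
    step reduces the axis with the larger absolute coordinate distance;
    on ties the row axis is reduced.  This deterministic tie-break makes
    the set of correct pointers a spanning tree rooted at the target.
    """
    if v == g.target:
        raise ValueError("target has no advice")
    if g.topology is Topology.LINE:
        return v + 1 if v < g.target else v - 1
    r, c = g.coords(v)
    tr, tc = g.coords(g.target)
    dr, dc = tr - r, tc - c
    if abs(dr) >= abs(dc) and dr != 0:
        return g.node_id(r + (1 if dr > 0 else -1), c)
    return g.node_id(r, c + (1 if dc > 0 else -1))


def _line_csr(n: int) -> tuple[np.ndarray, np.ndarray]:
    indptr = np.zeros(n + 1, dtype=np.int64)
    indices = []
    for v in range(n):
        nb = [u for u in (v - 1, v + 1) if 0 <= u < n]
        indices.extend(nb)
        indptr[v + 1] = indptr[v] + len(nb)
    return indptr, np.asarray(indices, dtype=np.int64)


def _grid_csr(side: int) -> tuple[np.ndarray, np.ndarray]:
    n = side * side
    indptr = np.zeros(n + 1, dtype=np.int64)
    indices = []
    for v in range(n):
        r, c = divmod(v, side)
        nb = []
        if r > 0:
            nb.append(v - side)
        if r < side - 1:
            nb.append(v + side)
        if c > 0:
            nb.append(v - 1)
        if c < side - 1:
            nb.append(v + 1)
        indices.extend(nb)
        indptr[v + 1] = indptr[v] + len(nb)
    return indptr, np.asarray(indices, dtype=np.int64)


def _correct_advice_all(g: AdviceGraph) -> np.ndarray:
    """Vector of tree-parents for every node (-1 at the target)."""
    nodes = np.arange(g.n_nodes)
    if g.topology is Topology.LINE:
        good = np.where(nodes < g.target, nodes + 1, nodes - 1)
    else:
        rows, cols = np.divmod(nodes, g.side)
        tr, tc = divmod(g.target, g.side)
        dr, dc = tr - rows, tc - cols
        step_row = (np.abs(dr) >= np.abs(dc)) & (dr != 0)
        good = np.where(
            step_row,
            (rows + np.sign(dr)) * g.side + cols,
            rows * g.side + cols + np.sign(dc),
        )
    good[g.target] = -1
    return good


def _draw_advice(g: AdviceGraph) -> None:
    """Fill g.advice in place: correct w.p. p, otherwise per wrong_model."""
    rng = np.random.default_rng(g.seed)
    good = _correct_advice_all(g)
    keep_correct = rng.random(g.n_nodes) < g.reliability
    if g.wrong_model is WrongModel.UNIFORM_NEIGHBOR:
        deg = np.diff(g.indptr)
        offset = (rng.random(g.n_nodes) * deg).astype(np.int64)
        wrong = g.indices[g.indptr[:-1] + offset]
    else:  # FLIP: the neighbor away from the target; single-neighbor ends
        nodes = np.arange(g.n_nodes)
        away = np.where(nodes < g.target, nodes - 1, nodes + 1)
        away = np.where(away < 0, 1, away)
        away = np.where(away >= g.n_nodes, g.n_nodes - 2, away)
        wrong = away
    advice = np.where(keep_correct, good, wrong)
    advice[g.target] = -1
    g.advice = advice.astype(np.int64)


def build_line_environment(
    n_nodes: int,
    reliability: float,
    wrong_model: WrongModel | str = WrongModel.UNIFORM_NEIGHBOR,
    seed: int = 0,
) -> AdviceGraph:
    """Line of ``n_nodes``; leftmost node is the conventional source, the
    rightmost node the target.

    Under ``flip`` the left-end node has a single neighbor, so its advice
    necessarily points to it (and is therefore correct); this degenerate
    case is kept as-is rather than special-cased away.
    """
    if n_nodes < 2:
        raise ValueError(f"a line environment needs at least 2 nodes, got {n_nodes}")
    if not 0.0 <= reliability <= 1.0:
        raise ValueError(f"reliability must lie in [0, 1], got {reliability}")
    wrong_model = WrongModel(wrong_model)
    indptr, indices = _line_csr(n_nodes)
    g = AdviceGraph(
        topology=Topology.LINE,
        n_nodes=n_nodes,
        target=n_nodes - 1,
        indptr=indptr,
        indices=indices,
        advice=np.empty(0, dtype=np.int64),
        reliability=float(reliability),
        wrong_model=wrong_model,
        seed=int(seed),
    )
    _draw_advice(g)
    return g


def build_grid_environment(side: int, reliability: float, seed: int = 0) -> AdviceGraph:
    """``side`` x ``side`` grid, 4-neighbor, no wraparound; the target sits
    next to the center at (side//2, side//2).

    Wrong advice is drawn uniformly over the node's neighbors (it may
    coincide with the correct pointer, so realized accuracy exceeds p).
    """
    if side < 2:
        raise ValueError(f"a grid environment needs side >= 2, got {side}")
    if not 0.0 <= reliability <= 1.0:
        raise ValueError(f"reliability must lie in [0, 1], got {reliability}")
    indptr, indices = _grid_csr(side)
    target = (side // 2) * side + (side // 2)
    g = AdviceGraph(
        topology=Topology.GRID,
        n_nodes=side * side,
        target=target,
        indptr=indptr,
        indices=indices,
        advice=np.empty(0, dtype=np.int64),
        reliability=float(reliability),
        wrong_model=WrongModel.UNIFORM_NEIGHBOR,
        seed=int(seed),
        side=side,
    )
    _draw_advice(g)
    return g


def advice_accuracy(g: AdviceGraph) -> float:
    """Fraction of non-target nodes whose advice equals the tree-parent."""
    good = _correct_advice_all(g)
    mask = np.arange(g.n_nodes) != g.target
    return float(np.count_nonzero(g.advice[mask] == good[mask]) / (g.n_nodes - 1))


# ---------------------------------------------------------------------------
# text serialization (one record per node, header with build parameters)

def save_environment(g: AdviceGraph, path: str | Path) -> None:
    lines = [
        f"# topology={g.topology.value} n_nodes={g.n_nodes} "
        f"side={'' if g.side is None else g.side} target={g.target} "
        f"reliability={g.reliability!r} wrong_model={g.wrong_model.value} seed={g.seed}",
        "id,neighbors,advice",
    ]
    for v in range(g.n_nodes):
        nb = "|".join(str(int(u)) for u in g.neighbors(v))
        lines.append(f"{v},{nb},{int(g.advice[v])}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_environment(path: str | Path) -> AdviceGraph:
    text = Path(path).read_text().splitlines()
    header = dict(
        item.split("=", 1) for item in text[0].lstrip("# ").split() if "=" in item
    )
    n = int(header["n_nodes"])
    indptr = np.zeros(n + 1, dtype=np.int64)
    indices: list[int] = []
    advice = np.full(n, -1, dtype=np.int64)
    for row in text[2:]:
        if not row.strip():
            continue
        vid, nb, adv = row.split(",")
        v = int(vid)
        nbs = [int(x) for x in nb.split("|") if x]
        indices.extend(nbs)
        indptr[v + 1] = len(nbs)
        advice[v] = int(adv)
    indptr = np.cumsum(indptr)
    side = int(header["side"]) if header.get("side") else None
    return AdviceGraph(
        topology=Topology(header["topology"]),
        n_nodes=n,
        target=int(header["target"]),
        indptr=indptr,
        indices=np.asarray(indices, dtype=np.int64),
        advice=advice,
        reliability=float(header["reliability"]),
        wrong_model=WrongModel(header["wrong_model"]),
        seed=int(header["seed"]),
        side=side,
    )
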