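"""s/t graph construction and exact min-cut via max-flow.

The segmentation graph has one node per in-mask voxel plus two terminals: the
source s (target-region terminal) and the sink t (background terminal).

Capacities (omega), with alpha the expansion factor:

  * t-link s -> i : alpha * R_i(background) — cut when i lands on the sink
    side, i.e. the price of labeling i background;
  * t-link i -> t : alpha * R_i(target);
  * n-link i <-> j : (1 - alpha) * W_ij, symmetric, between 8-neighbors.

With this wiring the capacity of any s/t cut equals the segmentation energy of
the induced labeling, so the minimum cut is the exact energy minimizer.

The solver is Dinic's algorithm (shortest-augmenting-path phases with
blocking flows) operating directly on float capacities; termination does not
depend on capacity integrality and residuals below 1e-12 are treated as
saturated. Ties among minimum cuts are broken deterministically by residual
reachability: nodes reachable from s in the residual graph are labeled
target. A from-scratch exhaustive-enumeration oracle is provided for
verification on small instances.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .energy import (
    BACKGROUND,
    TARGET,
    EnergyParams,
    SeedSets,
    regional_penalty,
    resolve_params,
)
from .errors import ConfigurationError, FormatError, InvalidInputError

__all__ = [
    "FlowGraph",
    "build_st_graph",
    "max_flow_min_cut",
    "brute_force_min_cut",
    "dump_flow_graph",
    "load_flow_graph",
]

SOURCE = "s"
SINK = "t"


@dataclass
class FlowGraph:
    """Directed capacitated s/t graph.

    Non-terminal node ids are arbitrary hashables (voxel tuples in the
    segmentation pipeline). n-links must be symmetric; t-links may have zero
    capacity but are present for every non-terminal node when built by
    :func:`build_st_graph`.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    source: object = SOURCE
    sink: object = SINK

    def __post_init__(self):
        self.graph.add_node(self.source)
        self.graph.add_node(self.sink)

    def add_node(self, node):
        if node in (self.source, self.sink):
            raise InvalidInputError("terminal ids are reserved")
        self.graph.add_node(node)

    def add_arc(self, u, v, capacity: float):
        if u == v:
            raise InvalidInputError("self-loops are not allowed")
        if not np.isfinite(capacity) or capacity < 0:
            raise InvalidInputError(f"capacity must be finite and nonnegative, got {capacity}")
        self.graph.add_edge(u, v, capacity=float(capacity))

    def add_t_links(self, node, from_source: float, to_sink: float):
        self.add_arc(self.source, node, from_source)
        self.add_arc(node, self.sink, to_sink)

    def add_n_link(self, u, v, capacity: float):
        """Symmetric neighbor link (equal capacity both directions)."""
        self.add_arc(u, v, capacity)
        self.add_arc(v, u, capacity)

    @property
    def interior_nodes(self):
        return [n for n in self.graph.nodes if n not in (self.source, self.sink)]


def build_st_graph(field_, seeds: SeedSets, params: EnergyParams, metric=None,
                   full_3d: bool = False):
    """Build the segmentation FlowGraph for a scalar or tensor field.

    Returns ``(flow_graph, resolved_params)``; the resolved parameters carry
    the data-adaptive sigma and instance K actually used.
    """
    if metric is not None:
        from dataclasses import replace

        params = replace(params, metric=metric if isinstance(metric, str) else metric.name)
    resolved, pairs, weights, dists = resolve_params(field_, seeds, params, full_3d)
    alpha = resolved.alpha

    g = FlowGraph()
    voxels = [tuple(v) for v in np.argwhere(field_.mask)]
    for i in voxels:
        g.add_node(i)
        r_bg = regional_penalty(i, BACKGROUND, seeds, dists, resolved)
        r_tg = regional_penalty(i, TARGET, seeds, dists, resolved)
        g.add_t_links(i, from_source=alpha * r_bg, to_sink=alpha * r_tg)
    for (i, j), w in zip(pairs, weights):
        g.add_n_link(i, j, (1.0 - alpha) * w)
    return g, resolved


#: Residual capacities at or below this are treated as saturated.
RESIDUAL_EPS = 1e-12


def _dinic(n: int, s: int, t: int, arcs):
    """Dinic's max-flow on an adjacency-list residual network.

    ``arcs`` is a list of (u, v, capacity) directed arcs with float
    capacities. Returns ``(flow_value, reachable)`` where ``reachable`` is the
    boolean residual-reachability vector from s after termination.
    """
    head = [[] for _ in range(n)]
    to = []
    cap = []
    for u, v, c in arcs:
        head[u].append(len(to))
        to.append(v)
        cap.append(float(c))
        head[v].append(len(to))
        to.append(u)
        cap.append(0.0)

    flow = 0.0
    level = [-1] * n
    while True:
        # BFS phase: level graph on the residual network
        level = [-1] * n
        level[s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for eid in head[u]:
                v = to[eid]
                if level[v] < 0 and cap[eid] > RESIDUAL_EPS:
                    level[v] = level[u] + 1
                    q.append(v)
        if level[t] < 0:
            break

        # blocking flow via iterative current-arc DFS
        it = [0] * n
        while True:
            stack = [s]
            path = []
            reached_t = False
            while stack:
                u = stack[-1]
                if u == t:
                    reached_t = True
                    break
                advanced = False
                while it[u] < len(head[u]):
                    eid = head[u][it[u]]
                    v = to[eid]
                    if cap[eid] > RESIDUAL_EPS and level[v] == level[u] + 1:
                        stack.append(v)
                        path.append(eid)
                        advanced = True
                        break
                    it[u] += 1
                if not advanced:
                    stack.pop()
                    if path:
                        path.pop()
                        it[stack[-1]] += 1
            if not reached_t:
                break
            bottleneck = min(cap[eid] for eid in path)
            for eid in path:
                cap[eid] -= bottleneck
                cap[eid ^ 1] += bottleneck
            flow += bottleneck

    reachable = [lv >= 0 for lv in level]
    return flow, reachable


def max_flow_min_cut(g: FlowGraph):
    """Exact maximum s->t flow and the induced minimum cut.

    Returns ``(flow_value, source_side)`` where ``source_side`` is the set of
    non-terminal nodes reachable from s in the residual graph (the
    deterministic tie-break; these receive the target label downstream). The
    flow value equals the returned cut's capacity by max-flow/min-cut duality
    (floating-point accumulation aside, well below 1e-9 on package-built
    instances).
    """
    nodes = [g.source] + g.interior_nodes + [g.sink]
    index = {node: k for k, node in enumerate(nodes)}
    arcs = [
        (index[u], index[v], a["capacity"])
        for u, v, a in g.graph.edges(data=True)
        if a["capacity"] > 0
    ]
    flow_value, reachable = _dinic(len(nodes), index[g.source], index[g.sink], arcs)
    source_side = frozenset(
        node
        for node, k in index.items()
        if reachable[k] and node not in (g.source, g.sink)
    )
    return float(flow_value), source_side


def cut_capacity(g: FlowGraph, source_side) -> float:
    """Capacity of the cut ({s} ∪ source_side, rest)."""
    s_side = set(source_side) | {g.source}
    return float(
        sum(
            attrs["capacity"]
            for u, v, attrs in g.graph.edges(data=True)
            if u in s_side and v not in s_side
        )
    )


BRUTE_FORCE_MAX_NODES = 20


def brute_force_min_cut(g: FlowGraph):
    """Exhaustive min-cut oracle: enumerate all 2^n source-side sets.

    Returns ``(min_value, optimal_cuts)`` with every argmin as a frozenset of
    non-terminal nodes. Refuses graphs with more than 20 non-terminal nodes.
    """
    nodes = sorted(g.interior_nodes, key=repr)
    n = len(nodes)
    if n > BRUTE_FORCE_MAX_NODES:
        raise ConfigurationError(
            f"brute-force enumeration refused: {n} > {BRUTE_FORCE_MAX_NODES} nodes"
        )
    bit = {node: k for k, node in enumerate(nodes)}

    # Encode each arc as (source-side membership tests) over all 2^n subsets.
    masks = np.arange(1 << n, dtype=np.int64)
    caps = np.zeros(1 << n)
    for u, v, attrs in g.graph.edges(data=True):
        c = attrs["capacity"]
        if c == 0:
            continue
        if u == g.sink or v == g.source:
            continue
        u_in = np.ones(1 << n, dtype=bool) if u == g.source else ((masks >> bit[u]) & 1).astype(bool)
        v_in = np.zeros(1 << n, dtype=bool) if v == g.sink else ((masks >> bit[v]) & 1).astype(bool)
        caps += c * (u_in & ~v_in)

    best = float(caps.min())
    arg = np.flatnonzero(caps == caps.min())
    cuts = [
        frozenset(node for node, k in bit.items() if (int(m) >> k) & 1) for m in arg
    ]
    return best, cuts


# ---------------------------------------------------------------------------
# Text dump/load (debugging and oracle replay)
# ---------------------------------------------------------------------------

_HEADER = "# tensorcut flow-graph v1"


def dump_flow_graph(g: FlowGraph, path):
    """Write the graph as a plain edge-list text file.

    Format: a header line, ``node <id>`` per non-terminal node, then
    ``arc <u> <v> <capacity>`` per directed arc, with terminals written as
    ``s`` and ``t``. Node ids are str()-ed; loading yields string ids.
    """
    def enc(n):
        if n == g.source:
            return "s"
        if n == g.sink:
            return "t"
        return str(n).replace(" ", "")

    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for n in g.interior_nodes:
            fh.write(f"node {enc(n)}\n")
        for u, v, attrs in g.graph.edges(data=True):
            fh.write(f"arc {enc(u)} {enc(v)} {attrs['capacity']!r}\n")


def load_flow_graph(path) -> FlowGraph:
    """Read a graph written by :func:`dump_flow_graph` (string node ids)."""
    g = FlowGraph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _HEADER:
            raise FormatError(f"not a tensorcut flow-graph file: {path}")
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "node" and len(parts) == 2:
                if parts[1] not in ("s", "t"):
                    g.add_node(parts[1])
            elif parts[0] == "arc" and len(parts) == 4:
                u = g.source if parts[1] == "s" else g.sink if parts[1] == "t" else parts[1]
                v = g.source if parts[2] == "s" else g.sink if parts[2] == "t" else parts[2]
                g.add_arc(u, v, float(parts[3]))
            else:
                raise FormatError(f"unrecognized line in flow-graph file: {line!r}")
    return g
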