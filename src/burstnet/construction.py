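"""Temporal-network construction on static underlying topologies.

The underlying topology constrains which pairs may interact.  A random
spanning tree (forest) is chosen; edges inside it are *trunks* and
edges outside it are *branches*.  Nodes and trunks are driven jointly,
root outward, through coupled two-node renewal updates so their
inter-event-time laws match the prescribed targets; each branch is
simply active whenever both of its endpoints are — so the activity of
the entire network is determined by its spanning tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .distributions import IETDistribution
from .errors import InconsistencyError, ParameterError
from .two_node import check_consistency

__all__ = [
    "SpanningTree",
    "TemporalNetwork",
    "TreeSimulator",
    "select_spanning_tree",
    "construct_static",
    "canonical_edge",
    "targets_from_sampler",
]


def canonical_edge(i, j):
    """Unordered edge as an ordered tuple."""
    return (i, j) if i <= j else (j, i)


@dataclass
class SpanningTree:
    """A rooted spanning forest of an underlying topology.

    ``parent`` maps every non-root node to its unique parent; roots map
    to ``None``.  ``layers[d]`` lists the nodes at hop distance ``d``
    from their component's root.  ``trunks`` are the tree edges and
    ``branches`` the remaining topology edges.
    """

    roots: list
    parent: dict
    layers: list = field(repr=False)
    trunks: set = field(repr=False)
    branches: set = field(repr=False)

    @property
    def root(self):
        return self.roots[0]

    def trunk_of(self, child):
        return canonical_edge(child, self.parent[child])

    def validate(self, graph: nx.Graph) -> None:
        """Raise if this is not a valid rooted spanning forest of ``graph``."""
        edges = {canonical_edge(*e) for e in graph.edges()}
        if self.trunks | self.branches != edges or self.trunks & self.branches:
            raise ParameterError("trunks/branches do not partition the edges")
        n_comp = nx.number_connected_components(graph)
        if len(self.trunks) != graph.number_of_nodes() - n_comp:
            raise ParameterError("trunk count != N - number of components")
        if len(self.roots) != n_comp:
            raise ParameterError("one root per component required")
        depth = {}
        for d, layer in enumerate(self.layers):
            for v in layer:
                depth[v] = d
        for v in graph.nodes():
            p = self.parent.get(v)
            if p is None:
                if v not in self.roots:
                    raise ParameterError(f"non-root node {v!r} has no parent")
                if depth.get(v) != 0:
                    raise ParameterError(f"root {v!r} not in layer 0")
            else:
                if canonical_edge(v, p) not in self.trunks:
                    raise ParameterError(f"parent link of {v!r} not a trunk")
                if depth.get(v) != depth.get(p, -2) + 1:
                    raise ParameterError(f"layer of {v!r} != parent layer + 1")


def select_spanning_tree(graph: nx.Graph, method: str = "uniform",
                         rng: np.random.Generator | None = None
                         ) -> SpanningTree:
    """Choose a spanning tree (forest, if disconnected) of ``graph``.

    ``uniform`` samples uniformly among all spanning trees of each
    component by Wilson's loop-erased random walk; ``bfs`` grows a
    breadth-first tree from a random root.  Each component gets an
    independently chosen random root.
    """
    if graph.number_of_nodes() == 0:
        raise ParameterError("topology must be nonempty")
    if method not in ("uniform", "bfs"):
        raise ParameterError(f"unknown tree method {method!r}")
    rng = np.random.default_rng() if rng is None else rng

    roots, parent = [], {}
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        root = nodes[int(rng.integers(len(nodes)))]
        roots.append(root)
        parent[root] = None
        if method == "uniform":
            _wilson_component(graph, nodes, root, parent, rng)
        else:
            for par, child in nx.bfs_edges(graph, root):
                parent[child] = par
    return _finalize_tree(graph, roots, parent)


def _wilson_component(graph, nodes, root, parent, rng):
    """Wilson's algorithm: loop-erased random walks to the current tree."""
    in_tree = {root}
    for start in nodes:
        if start in in_tree:
            continue
        path = [start]
        pos = {start: 0}
        while path[-1] not in in_tree:
            nbrs = list(graph.adj[path[-1]])
            nxt = nbrs[int(rng.integers(len(nbrs)))]
            if nxt in pos:  # erase the loop
                cut = pos[nxt] + 1
                for v in path[cut:]:
                    del pos[v]
                del path[cut:]
            else:
                pos[nxt] = len(path)
                path.append(nxt)
        for a, b in zip(path[:-1], path[1:]):
            parent[a] = b
            in_tree.add(a)


def _finalize_tree(graph, roots, parent) -> SpanningTree:
    children = {}
    for child, par in parent.items():
        if par is not None:
            children.setdefault(par, []).append(child)
    layers = [list(roots)]
    while True:
        nxt = [c for v in layers[-1] for c in children.get(v, [])]
        if not nxt:
            break
        layers.append(nxt)
    trunks = {canonical_edge(c, p) for c, p in parent.items() if p is not None}
    branches = {canonical_edge(*e) for e in graph.edges()} - trunks
    tree = SpanningTree(roots=roots, parent=parent, layers=layers,
                        trunks=trunks, branches=branches)
    tree.validate(graph)
    return tree


# ---------------------------------------------------------------------------
# temporal network container
# ---------------------------------------------------------------------------

@dataclass
class TemporalNetwork:
    """Activity of all nodes over an underlying topology with its tree.

    ``node_states[t, k]`` is the state of the node in column ``k`` at
    time ``t`` (t = 0..t_tol, all-active at t = 0).  Link states are
    derived on demand: a link is active exactly when both endpoints are
    (true for trunks by the coupling and for branches by definition).
    ``birth[k]`` is the time node ``k`` entered the system and
    ``edge_birth`` the per-edge entry times (all zero on static
    topologies).
    """

    graph: nx.Graph
    tree: SpanningTree
    t_tol: int
    columns: dict = field(repr=False)           # node id -> column
    node_states: np.ndarray = field(repr=False)  # (t_tol + 1, N) bool
    birth: np.ndarray = field(repr=False)
    edge_birth: dict = field(repr=False, default_factory=dict)
    # per-edge presence windows [start, end) for edges that were ever
    # deleted; edges absent from this map live over [edge_birth, t_tol]
    edge_intervals: dict = field(repr=False, default_factory=dict)

    @property
    def node_ids(self):
        return list(self.columns)

    def node_series(self, i) -> np.ndarray:
        return self.node_states[:, self.columns[i]]

    def link_series(self, i, j) -> np.ndarray:
        e = canonical_edge(i, j)
        if not self.graph.has_edge(*e) and e not in self.edge_intervals:
            raise ParameterError(f"no edge {e!r} in the underlying topology")
        s = self.node_states[:, self.columns[i]] \
            & self.node_states[:, self.columns[j]]
        mask = np.zeros(len(s), dtype=bool)
        for a, b in self._intervals(e):
            mask[a:b] = True
        return s & mask

    def _intervals(self, e):
        if e in self.edge_intervals:
            return self.edge_intervals[e]
        return [(self.edge_birth.get(e, 0), self.t_tol + 1)]

    def edge_present(self, e, t: int) -> bool:
        return any(a <= t < b for a, b in self._intervals(e))

    def all_edges(self) -> set:
        """Every edge that ever existed, canonically ordered."""
        edges = {canonical_edge(*e) for e in self.graph.edges()}
        edges.update(self.edge_intervals)
        return edges

    def active_edges(self, t: int) -> set:
        row = self.node_states[t]
        return {e for e in self.all_edges()
                if self.edge_present(e, t)
                and row[self.columns[e[0]]] and row[self.columns[e[1]]]}

    def activation_times(self, i) -> np.ndarray:
        return np.flatnonzero(self.node_series(i))


# ---------------------------------------------------------------------------
# simulation engine
# ---------------------------------------------------------------------------

def layer_step(t, rng, layer_cols, parent_col, node_tab, node_idx,
               trunk_tab, trunk_idx, last_node, last_trunk, n):
    """One synchronous update of all nodes/trunks, root layer outward.

    Every unit's hazard is evaluated at its pre-step waiting time; a
    child activates with probability ``p1 / h_parent`` when its parent
    is active and ``p3 / (1 - h_parent)`` otherwise.  Trunk activation
    (product of endpoints) is recorded into ``last_trunk`` in place;
    node ``last_node`` is left to the caller.  Returns the new state row.
    Raises :class:`InconsistencyError` (with ``unit`` = offending child
    column) when a joint probability is negative beyond rounding noise.
    """
    u = rng.random(n)
    h_node = node_tab[node_idx, t - last_node]
    active = np.zeros(n, dtype=bool)
    rc = layer_cols[0]
    active[rc] = u[rc] < h_node[rc]
    for cols in layer_cols[1:]:
        par = parent_col[cols]
        hx = h_node[par]
        hy = h_node[cols]
        hz = trunk_tab[trunk_idx[cols], t - last_trunk[cols]]
        for name, arr in (("p2", hx - hz), ("p3", hy - hz),
                          ("p4", 1.0 + hz - hx - hy)):
            k = int(np.argmin(arr))
            if arr[k] < -1e-12:
                raise InconsistencyError(
                    f"{name} = {arr[k]:.6g} < 0 at time {t}",
                    time=t, unit=int(cols[k]),
                    probabilities=(float(hz[k]), float(hx[k] - hz[k]),
                                   float(hy[k] - hz[k]),
                                   float(1.0 + hz[k] - hx[k] - hy[k])))
        pa = active[par]
        q = np.where(pa,
                     hz / np.where(hx > 0, hx, 1.0),
                     (hy - hz) / np.where(hx < 1, 1.0 - hx, 1.0))
        act = u[cols] < np.clip(q, 0.0, 1.0)
        active[cols] = act
        last_trunk[cols[act & pa]] = t
    return active


def _resolve_targets(units, targets, what):
    if isinstance(targets, IETDistribution):
        mapping = {u: targets for u in units}
    else:
        mapping = dict(targets)
        missing = [u for u in units if u not in mapping]
        if missing:
            raise ParameterError(f"no {what} target for {missing[:5]!r}...")
    return mapping


def targets_from_sampler(units, kind, exponent_sampler, support_max,
                         rng: np.random.Generator):
    """Per-unit targets with exponents drawn from ``exponent_sampler(rng)``."""
    from .distributions import make_distribution
    return {u: make_distribution(kind, float(exponent_sampler(rng)),
                                 support_max)
            for u in units}


class TreeSimulator:
    """Step-by-step driver of node and trunk activity on a spanning tree.

    Advances all units one time step per :meth:`step`: the root(s)
    activate with their own hazard; then, layer by layer outward, each
    child is updated within the two-node system formed with its parent
    and the trunk between them; trunk states follow as the product of
    the endpoint states.  Vectorized over each layer.
    """

    def __init__(self, graph: nx.Graph, tree: SpanningTree, node_targets,
                 trunk_targets, t_tol: int,
                 rng: np.random.Generator | None = None,
                 precheck: bool = True):
        if t_tol < 1:
            raise ParameterError("t_tol must be >= 1")
        self.graph = graph
        self.tree = tree
        self.t_tol = int(t_tol)
        self.rng = np.random.default_rng() if rng is None else rng

        nodes = [v for layer in tree.layers for v in layer]
        self.columns = {v: k for k, v in enumerate(nodes)}
        n = len(nodes)
        self.node_targets = _resolve_targets(nodes, node_targets, "node")
        self.trunk_targets = _resolve_targets(
            sorted(tree.trunks), trunk_targets, "trunk")
        if precheck:
            self._precheck()

        self._node_tab, node_idx = self._hazard_matrix(
            [self.node_targets[v] for v in nodes])
        trunk_dists = [self.trunk_targets[tree.trunk_of(v)] if
                       tree.parent[v] is not None else None for v in nodes]
        self._trunk_tab, trunk_idx = self._hazard_matrix(
            [d for d in trunk_dists if d is not None])
        ti, k = np.zeros(n, dtype=np.int64), 0
        for col, d in enumerate(trunk_dists):
            if d is not None:
                ti[col] = trunk_idx[k]
                k += 1
        self._node_idx = node_idx
        self._trunk_idx = ti

        self._layer_cols = [np.array([self.columns[v] for v in layer],
                                     dtype=np.int64)
                            for layer in tree.layers]
        par = np.full(n, -1, dtype=np.int64)
        for v in nodes:
            p = tree.parent[v]
            if p is not None:
                par[self.columns[v]] = self.columns[p]
        self._parent_col = par

        self.t = 0
        self.node_states = np.zeros((self.t_tol + 1, n), dtype=bool)
        self.node_states[0] = True
        self._last_node = np.zeros(n, dtype=np.int64)
        self._last_trunk = np.zeros(n, dtype=np.int64)  # indexed by child col

    def _precheck(self):
        """Check consistency of every distinct (F, G, H) combination."""
        seen = set()
        for child in self.tree.parent:
            p = self.tree.parent[child]
            if p is None:
                continue
            F = self.node_targets[p]
            G = self.node_targets[child]
            H = self.trunk_targets[self.tree.trunk_of(child)]
            key = (id(F), id(G), id(H))
            if key in seen:
                continue
            seen.add(key)
            verdict = _auto_check(F, G, H)
            if not verdict.consistent:
                raise InconsistencyError(
                    f"targets on trunk {self.tree.trunk_of(child)} are "
                    f"inconsistent: {verdict.detail}",
                    unit=self.tree.trunk_of(child))

    def _hazard_matrix(self, dists):
        """Stack hazard tables of the distinct distributions in ``dists``."""
        distinct, index = [], []
        ids = {}
        for d in dists:
            k = ids.get(id(d))
            if k is None:
                k = ids[id(d)] = len(distinct)
                distinct.append(d)
            index.append(k)
        max_gap = self.t_tol + 1
        if not distinct:
            return np.ones((1, max_gap + 1)), np.zeros(0, dtype=np.int64)
        tab = np.vstack([d.hazard_table(max_gap) for d in distinct])
        return tab, np.asarray(index, dtype=np.int64)

    def step(self) -> np.ndarray:
        """Advance every node and trunk by one time step; returns the new
        node-state row."""
        if self.t >= self.t_tol:
            raise ParameterError("horizon t_tol already reached")
        t = self.t + 1
        try:
            active = layer_step(
                t, self.rng, self._layer_cols, self._parent_col,
                self._node_tab, self._node_idx, self._trunk_tab,
                self._trunk_idx, self._last_node, self._last_trunk,
                self.node_states.shape[1])
        except InconsistencyError as err:
            child = self._col_node(err.unit)
            raise InconsistencyError(
                f"{err} on trunk {self.tree.trunk_of(child)}",
                time=t, unit=self.tree.trunk_of(child),
                probabilities=err.probabilities,
                trajectories=self.node_states[:t]) from None
        self.node_states[t] = active
        self._last_node[active] = t
        self.t = t
        return active

    def _col_node(self, col):
        for v, k in self.columns.items():
            if k == col:
                return v
        raise KeyError(col)

    def run(self) -> TemporalNetwork:
        while self.t < self.t_tol:
            self.step()
        return self.result()

    def result(self) -> TemporalNetwork:
        n = self.node_states.shape[1]
        return TemporalNetwork(
            graph=self.graph, tree=self.tree, t_tol=self.t,
            columns=dict(self.columns),
            node_states=self.node_states[:self.t + 1],
            birth=np.zeros(n, dtype=np.int64))


def _auto_check(F, G, H):
    if F.kind == G.kind == H.kind == "power_law" and F.exponent == G.exponent:
        return check_consistency(F, G, H, mode="bursty_analytic")
    if (F.kind == G.kind == H.kind == "discrete_exponential"
            and F.exponent == G.exponent):
        return check_consistency(F, G, H, mode="poisson_analytic")
    return check_consistency(F, G, H, mode="enumerate", horizon=12)


def construct_static(topology: nx.Graph, node_targets, trunk_targets,
                     t_tol: int, seed=None, tree_method: str = "uniform",
                     precheck: bool = True) -> TemporalNetwork:
    """Build a full temporal network of length ``t_tol`` on a static topology.

    ``node_targets`` / ``trunk_targets`` may each be a single
    :class:`IETDistribution` (common target) or a mapping from unit
    (node id / canonical trunk edge) to its distribution.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    tree = select_spanning_tree(topology, method=tree_method, rng=rng)
    sim = TreeSimulator(topology, tree, node_targets, trunk_targets,
                        t_tol, rng=rng, precheck=precheck)
    return sim.run()
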