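"""Temporal networks on time-varying underlying topologies.

Two drivers are provided.  :func:`construct_temporal_ba` interleaves
one activity step with one degree-preferential growth step (a "temporal
Barabasi-Albert" model): every new node arrives active with ``m`` new
links, one of which — chosen uniformly — extends the spanning tree.
:func:`construct_time_varying` replays an arbitrary sequence of
topology deltas (node/edge additions and removals), repairing the
spanning tree after every change before advancing the activity by one
step.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .construction import (SpanningTree, TemporalNetwork, _resolve_targets,
                           canonical_edge, layer_step, select_spanning_tree)
from .distributions import IETDistribution
from .errors import ParameterError

__all__ = [
    "TemporalBAConfig",
    "construct_temporal_ba",
    "construct_time_varying",
]


@dataclass
class TemporalBAConfig:
    """Parameters of the temporal preferential-attachment model."""

    m0: int
    m: int
    final_N: int
    g: int
    node_target: IETDistribution = None
    trunk_target: IETDistribution = None
    tree_method: str = "uniform"

    def __post_init__(self):
        if not (1 <= self.m <= self.m0 < self.final_N):
            raise ParameterError("need 1 <= m <= m0 < final_N")
        if self.g < 0:
            raise ParameterError("g must be >= 0")

    @property
    def total_steps(self) -> int:
        return (self.final_N - self.m0) + self.g


def _layers_from_depth(depth, columns):
    if not depth:
        return [np.zeros(0, dtype=np.int64)]
    nlay = max(depth.values()) + 1
    layers = [[] for _ in range(nlay)]
    for v, d in depth.items():
        layers[d].append(columns[v])
    return [np.asarray(sorted(l), dtype=np.int64) for l in layers]


def construct_temporal_ba(config: TemporalBAConfig, seed=None
                          ) -> TemporalNetwork:
    """Grow a preferential-attachment topology while driving activity.

    Each step first advances all existing units one activity step on the
    current spanning tree, then (during the growth phase) attaches one
    new node with ``m`` degree-preferential links.  The new node, its
    links — and hence the chosen endpoints — start active.  After the
    topology reaches ``final_N`` nodes, ``g`` activity-only steps follow.
    """
    cfg = config
    if cfg.node_target is None or cfg.trunk_target is None:
        raise ParameterError("node_target and trunk_target are required")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    T = cfg.total_steps
    N = cfg.final_N
    columns = {i: i for i in range(N)}

    graph = nx.complete_graph(cfg.m0)
    tree0 = select_spanning_tree(graph, method=cfg.tree_method, rng=rng)
    parent = dict(tree0.parent)
    depth = {v: d for d, layer in enumerate(tree0.layers) for v in layer}

    node_tab = cfg.node_target.hazard_table(T + 1)[None, :]
    trunk_tab = cfg.trunk_target.hazard_table(T + 1)[None, :]
    node_idx = np.zeros(N, dtype=np.int64)
    trunk_idx = np.zeros(N, dtype=np.int64)

    states = np.zeros((T + 1, N), dtype=bool)
    states[0, :cfg.m0] = True
    birth = np.zeros(N, dtype=np.int64)
    edge_birth = {canonical_edge(*e): 0 for e in graph.edges()}
    last_node = np.zeros(N, dtype=np.int64)
    last_trunk = np.zeros(N, dtype=np.int64)

    # degree-proportional sampling pool: each node repeated by its degree
    pool = [v for e in graph.edges() for v in e]
    parent_col = np.full(N, -1, dtype=np.int64)
    for v, p in parent.items():
        if p is not None:
            parent_col[v] = p
    layer_cols = _layers_from_depth(depth, columns)
    alive = cfg.m0

    for t in range(1, T + 1):
        active = layer_step(t, rng, layer_cols, parent_col, node_tab,
                            node_idx, trunk_tab, trunk_idx,
                            last_node, last_trunk, N)
        states[t] = active
        last_node[active] = t
        if alive < N:
            j = alive
            targets = _preferential_targets(pool, cfg.m, alive, rng)
            graph.add_node(j)
            for s in targets:
                graph.add_edge(j, s)
                edge_birth[canonical_edge(j, s)] = t
            birth[j] = t
            states[t, j] = True
            last_node[j] = t
            forced = [s for s in targets if not states[t, s]]
            states[t, forced] = True
            last_node[forced] = t
            attach = targets[int(rng.integers(len(targets)))]
            parent[j] = attach
            depth[j] = depth[attach] + 1
            parent_col[j] = attach
            pool.extend(targets)
            pool.extend([j] * cfg.m)
            alive += 1
            layer_cols = _layers_from_depth(depth, columns)
            # forcing may have flipped trunk products to active
            _refresh_trunk_clocks(states[t], parent_col, last_trunk, t, alive)

    trunks = {canonical_edge(v, p) for v, p in parent.items() if p is not None}
    tree = SpanningTree(
        roots=[v for v, p in parent.items() if p is None],
        parent=parent,
        layers=[[int(c) for c in cols] for cols in layer_cols],
        trunks=trunks,
        branches={canonical_edge(*e) for e in graph.edges()} - trunks)
    tree.validate(graph)
    return TemporalNetwork(graph=graph, tree=tree, t_tol=T, columns=columns,
                           node_states=states, birth=birth,
                           edge_birth=edge_birth)


def _preferential_targets(pool, m, n_existing, rng):
    if m > n_existing:
        raise ParameterError("cannot attach more links than existing nodes")
    chosen = []
    seen = set()
    while len(chosen) < m:
        if pool:
            v = pool[int(rng.integers(len(pool)))]
        else:  # single isolated seed node
            v = int(rng.integers(n_existing))
        if v not in seen:
            seen.add(v)
            chosen.append(v)
    return chosen


def _refresh_trunk_clocks(row, parent_col, last_trunk, t, n_alive):
    cols = np.flatnonzero(parent_col[:n_alive] >= 0)
    both = row[cols] & row[parent_col[cols]]
    last_trunk[cols[both]] = t


# ---------------------------------------------------------------------------
# general time-varying topologies
# ---------------------------------------------------------------------------

class _EvolvingState:
    """Mutable topology + spanning forest, with repair operations."""

    def __init__(self, graph, parent, depth):
        self.graph = graph
        self.parent = parent        # node -> parent or None
        self.depth = depth          # node -> hop distance from its root

    def trunks(self):
        return {canonical_edge(v, p) for v, p in self.parent.items()
                if p is not None}

    def children_map(self):
        ch = {}
        for v, p in self.parent.items():
            if p is not None:
                ch.setdefault(p, []).append(v)
        return ch

    def subtree(self, top):
        ch = self.children_map()
        out, stack = [], [top]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(ch.get(v, []))
        return out

    def reroot(self, new_root):
        """Reverse parent pointers along the path new_root -> old root."""
        path = [new_root]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        for a, b in zip(path[:-1], path[1:]):
            self.parent[b] = a
        self.parent[new_root] = None

    def recompute_depths(self):
        self.depth = {}
        ch = self.children_map()
        for root in [v for v, p in self.parent.items() if p is None]:
            stack = [(root, 0)]
            while stack:
                v, d = stack.pop()
                self.depth[v] = d
                stack.extend((c, d + 1) for c in ch.get(v, []))

    # -- delta operations ---------------------------------------------

    def add_node(self, v):
        if self.graph.has_node(v):
            raise ParameterError(f"node {v!r} already present")
        self.graph.add_node(v)
        self.parent[v] = None

    def add_edge(self, u, v, rng):
        """Returns True if the new edge was adopted as a trunk."""
        for w in (u, v):
            if not self.graph.has_node(w):
                raise ParameterError(f"edge endpoint {w!r} unknown")
        if self.graph.has_edge(u, v) or u == v:
            raise ParameterError(f"invalid or duplicate edge ({u!r}, {v!r})")
        merging = not nx.has_path(self.graph, u, v)
        self.graph.add_edge(u, v)
        if merging:
            # adopt as trunk: re-root v's component beneath u
            self.reroot(v)
            self.parent[v] = u
            return True
        return False

    def del_edge(self, u, v, rng):
        """Returns the branch edge promoted to trunk during repair, if any."""
        if not self.graph.has_edge(u, v):
            raise ParameterError(f"edge ({u!r}, {v!r}) not present")
        is_trunk = canonical_edge(u, v) in self.trunks()
        self.graph.remove_edge(u, v)
        if not is_trunk:
            return None
        child = u if self.parent.get(u) == v else v
        self.parent[child] = None  # detach the orphan subtree first
        orphans = set(self.subtree(child))
        crossing = [(a, b) for a in orphans for b in self.graph.adj[a]
                    if b not in orphans]
        if not crossing:
            return None  # orphan side becomes its own component
        a, b = crossing[int(rng.integers(len(crossing)))]
        self.reroot(a)  # stays inside the orphan subtree
        self.parent[a] = b
        return canonical_edge(a, b)

    def del_node(self, v, rng):
        promoted = []
        for w in list(self.graph.adj[v]):
            e = self.del_edge(v, w, rng)
            if e is not None:
                promoted.append(e)
        self.graph.remove_node(v)
        del self.parent[v]
        return promoted


def construct_time_varying(initial_topology: nx.Graph, deltas, node_targets,
                           trunk_targets, t_tol: int, seed=None,
                           tree_method: str = "uniform",
                           validate_each_step: bool = False
                           ) -> TemporalNetwork:
    """Drive activity over an explicit sequence of topology changes.

    ``deltas`` is an iterable of dicts ``{"t": step, "add_nodes": [...],
    "add_edges": [...], "del_edges": [...], "del_nodes": [...]}``.  At
    each step the deltas scheduled for that time are applied first and
    the spanning forest repaired (an orphaned subtree is re-attached
    through a uniformly chosen surviving edge, else becomes its own
    tree); then all units advance one activity step.  Newly added nodes
    (with their attachment links) start active.
    """
    if t_tol < 1:
        raise ParameterError("t_tol must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    deltas = [dict(d) for d in deltas]
    by_time = {}
    for d in deltas:
        by_time.setdefault(int(d["t"]), []).append(d)

    all_nodes = list(initial_topology.nodes())
    known = set(all_nodes)
    for d in deltas:
        for v in d.get("add_nodes", ()):
            if v not in known:
                known.add(v)
                all_nodes.append(v)
    columns = {v: k for k, v in enumerate(all_nodes)}
    N = len(all_nodes)

    graph = nx.Graph()
    graph.add_nodes_from(initial_topology.nodes())
    graph.add_edges_from(initial_topology.edges())
    tree0 = select_spanning_tree(graph, method=tree_method, rng=rng)
    state = _EvolvingState(graph, dict(tree0.parent),
                           {v: d for d, layer in enumerate(tree0.layers)
                            for v in layer})

    node_map = _resolve_targets(all_nodes, node_targets, "node")
    possible_edges = {canonical_edge(*e) for e in graph.edges()}
    for d in deltas:
        possible_edges.update(canonical_edge(*e)
                              for e in d.get("add_edges", ()))
    trunk_map = _resolve_targets(sorted(possible_edges), trunk_targets,
                                 "trunk")
    node_tab, node_idx = _stack_tables(
        [node_map[v] for v in all_nodes], t_tol)
    trunk_tab, trunk_dist_of = _stack_tables(
        [trunk_map[e] for e in sorted(possible_edges)], t_tol)
    trunk_dist_of = dict(zip(sorted(possible_edges), trunk_dist_of))

    states = np.zeros((t_tol + 1, N), dtype=bool)
    birth = np.zeros(N, dtype=np.int64)
    open_intervals = {canonical_edge(*e): 0 for e in graph.edges()}
    closed_intervals = {}
    states[0, [columns[v] for v in graph.nodes()]] = True
    last_node = np.zeros(N, dtype=np.int64)
    last_trunk = np.zeros(N, dtype=np.int64)

    def rebuild_arrays():
        parent_col = np.full(N, -1, dtype=np.int64)
        trunk_idx = np.zeros(N, dtype=np.int64)
        for v, p in state.parent.items():
            if p is not None:
                c = columns[v]
                parent_col[c] = columns[p]
                trunk_idx[c] = trunk_dist_of[canonical_edge(v, p)]
        layer_cols = _layers_from_depth(
            {v: d for v, d in state.depth.items()}, columns)
        return parent_col, trunk_idx, layer_cols

    def reset_trunk_clock(child, t):
        """Clock of a child's (possibly new) trunk: the last time both
        endpoints were simultaneously active.  Never ahead of either
        endpoint's own clock, so the link's waiting time stays >= both
        node waiting times (a link cannot activate without its ends)."""
        e = canonical_edge(child, state.parent[child])
        ci, cj = columns[e[0]], columns[e[1]]
        hits = np.flatnonzero(states[:t, ci] & states[:t, cj])
        last_trunk[columns[child]] = hits[-1] if len(hits) \
            else min(last_node[ci], last_node[cj])

    state.recompute_depths()
    parent_col, trunk_idx, layer_cols = rebuild_arrays()

    for t in range(1, t_tol + 1):
        new_nodes = []
        if t in by_time:
            old_parent = dict(state.parent)
            for d in by_time[t]:
                for v in d.get("add_nodes", ()):
                    state.add_node(v)
                    birth[columns[v]] = t
                    new_nodes.append(v)
                for u, v in d.get("add_edges", ()):
                    state.add_edge(u, v, rng)
                    open_intervals[canonical_edge(u, v)] = t
                for u, v in d.get("del_edges", ()):
                    state.del_edge(u, v, rng)
                    e = canonical_edge(u, v)
                    closed_intervals.setdefault(e, []).append(
                        (open_intervals.pop(e), t))
                for v in d.get("del_nodes", ()):
                    for w in list(state.graph.adj[v]):
                        e = canonical_edge(v, w)
                        closed_intervals.setdefault(e, []).append(
                            (open_intervals.pop(e), t))
                    state.del_node(v, rng)
            state.recompute_depths()
            parent_col, trunk_idx, layer_cols = rebuild_arrays()
            for v, p in state.parent.items():
                if p is not None and old_parent.get(v) != p:
                    reset_trunk_clock(v, t)
        active = layer_step(t, rng, layer_cols, parent_col, node_tab,
                            node_idx, trunk_tab, trunk_idx,
                            last_node, last_trunk, N)
        states[t] = active
        last_node[active] = t
        if new_nodes:
            forced = [columns[v] for v in new_nodes]
            # a node arriving with attachment edges activates them too
            forced += [columns[w] for v in new_nodes
                       for w in state.graph.adj[v] if not states[t, columns[w]]]
            states[t, forced] = True
            last_node[forced] = t
            _refresh_trunk_clocks(states[t], parent_col, last_trunk, t, N)
        if validate_each_step:
            _current_tree(state).validate(state.graph)

    tree = _current_tree(state)
    intervals = {e: ivs for e, ivs in closed_intervals.items()}
    for e, start in open_intervals.items():
        intervals.setdefault(e, []).append((start, t_tol + 1))
    return TemporalNetwork(graph=state.graph, tree=tree, t_tol=t_tol,
                           columns=columns, node_states=states, birth=birth,
                           edge_birth={e: iv[0][0]
                                       for e, iv in intervals.items()},
                           edge_intervals=intervals)


def _stack_tables(dists, t_tol):
    distinct, index, ids = [], [], {}
    for d in dists:
        k = ids.get(id(d))
        if k is None:
            k = ids[id(d)] = len(distinct)
            distinct.append(d)
        index.append(k)
    tab = np.vstack([d.hazard_table(t_tol + 1) for d in distinct]) \
        if distinct else np.ones((1, t_tol + 2))
    return tab, np.asarray(index, dtype=np.int64)


def _current_tree(state: _EvolvingState) -> SpanningTree:
    state.recompute_depths()
    trunks = state.trunks()
    nlay = max(state.depth.values(), default=0) + 1
    layers = [[] for _ in range(nlay)]
    for v, d in sorted(state.depth.items(), key=lambda kv: str(kv[0])):
        layers[d].append(v)
    return SpanningTree(
        roots=[v for v, p in state.parent.items() if p is None],
        parent=dict(state.parent), layers=layers, trunks=trunks,
        branches={canonical_edge(*e)
                  for e in state.graph.edges()} - trunks)
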