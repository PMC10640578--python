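"""Contact-stream file formats and topology input.

Contacts are timestamped triplets ``(t, i, j)`` — one active link per
line — matching the whitespace-separated format of published
face-to-face contact datasets.  Reading compresses raw timestamps to
consecutive integer steps (one per distinct timestamp, starting at 1)
and remaps node ids densely.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .construction import TemporalNetwork, canonical_edge
from .errors import ParameterError

__all__ = [
    "ContactEvent",
    "ContactData",
    "write_contacts",
    "write_activity",
    "read_contacts",
    "build_topology_from_events",
    "read_edge_list",
    "read_topology_deltas",
]


@dataclass(frozen=True, order=True)
class ContactEvent:
    t: int
    i: int
    j: int

    def __post_init__(self):
        if self.t < 1:
            raise ParameterError("timestep must be >= 1")
        if self.i == self.j:
            raise ParameterError("self-contact is not allowed")
        if self.i > self.j:
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)


@dataclass
class ContactData:
    """Events with dense ids and compressed steps, plus the mappings."""

    events: list
    node_map: dict    # original id -> dense 0-based id
    time_map: dict    # raw timestamp -> 1-based step

    @property
    def t_tol(self) -> int:
        return len(self.time_map)

    @property
    def n_nodes(self) -> int:
        return len(self.node_map)


def write_contacts(net: TemporalNetwork, path) -> int:
    """Write one ``t<TAB>i<TAB>j`` line per active link per step.

    Lines are sorted by step then canonical edge; returns the line count.
    """
    edges = sorted(net.all_edges())
    S = net.node_states[1:]
    ci = np.array([net.columns[e[0]] for e in edges], dtype=np.int64)
    cj = np.array([net.columns[e[1]] for e in edges], dtype=np.int64)
    co = S[:, ci] & S[:, cj]
    for k, e in enumerate(edges):
        present = np.zeros(net.t_tol, dtype=bool)
        for a, b in net._intervals(e):
            present[max(a - 1, 0):b - 1] = True
        co[:, k] &= present
    n = 0
    with open(path, "w") as fh:
        for trow, erow in zip(*np.nonzero(co)):
            e = edges[erow]
            fh.write(f"{trow + 1}\t{e[0]}\t{e[1]}\n")
            n += 1
    return n


def write_activity(net: TemporalNetwork, path) -> int:
    """Per-node activity table ``t<TAB>node<TAB>state`` for t >= 1."""
    n = 0
    with open(path, "w") as fh:
        for t in range(1, net.t_tol + 1):
            row = net.node_states[t]
            for i in net.node_ids:
                fh.write(f"{t}\t{i}\t{int(row[net.columns[i]])}\n")
                n += 1
    return n


def read_contacts(path, dialect: str = "triplet") -> ContactData:
    """Parse a whitespace-separated contact file.

    ``triplet`` expects exactly three columns ``t i j``; the
    ``sociopatterns`` dialect tolerates extra metadata columns and raw
    epoch timestamps.  Self-contacts are skipped with a warning;
    duplicate triplets collapse to one event.
    """
    if dialect not in ("triplet", "sociopatterns"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    raw = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3 or (dialect == "triplet" and len(parts) != 3):
                raise ParameterError(f"line {ln}: expected 't i j', got "
                                     f"{line.rstrip()!r}")
            try:
                t = int(parts[0])
            except ValueError:
                raise ParameterError(f"line {ln}: non-integer timestamp in "
                                     f"{line.rstrip()!r}") from None
            i, j = parts[1], parts[2]
            try:
                i, j = int(i), int(j)  # numeric ids sort numerically
            except ValueError:
                pass
            if i == j:
                warnings.warn(f"line {ln}: self-contact {i!r} skipped")
                continue
            raw.add((t, i, j) if i <= j else (t, j, i))
    times = sorted({t for t, _, _ in raw})
    time_map = {t: k + 1 for k, t in enumerate(times)}
    ids = sorted({v for _, i, j in raw for v in (i, j)})
    node_map = {v: k for k, v in enumerate(ids)}
    events = sorted(ContactEvent(time_map[t], node_map[i], node_map[j])
                    for t, i, j in raw)
    return ContactData(events=events, node_map=node_map, time_map=time_map)


def build_topology_from_events(events) -> nx.Graph:
    """Aggregate contacts: an edge exists if the pair ever interacted."""
    graph = nx.Graph()
    for ev in events:
        graph.add_edge(*canonical_edge(ev.i, ev.j))
    return graph


def read_edge_list(path) -> nx.Graph:
    """Two-column whitespace-separated edge list with integer node ids."""
    graph = nx.Graph()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise ParameterError(f"line {ln}: expected 'i j'")
            i, j = int(parts[0]), int(parts[1])
            if i == j:
                raise ParameterError(f"line {ln}: self-loop {i}")
            graph.add_edge(*canonical_edge(i, j))
    return graph


def read_topology_deltas(path) -> list:
    """JSON-lines topology deltas for the time-varying driver."""
    deltas = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as err:
                raise ParameterError(f"line {ln}: invalid JSON: {err}") \
                    from None
            if "t" not in d:
                raise ParameterError(f"line {ln}: delta missing 't'")
            d["add_edges"] = [tuple(e) for e in d.get("add_edges", [])]
            d["del_edges"] = [tuple(e) for e in d.get("del_edges", [])]
            deltas.append(d)
    return deltas
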