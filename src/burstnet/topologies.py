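"""Seeded generators for the underlying-topology families used in tests
and experiments."""

from __future__ import annotations

import networkx as nx
import numpy as np

from .errors import ParameterError

__all__ = ["generate_fixture_topology"]

_FAMILIES = ("ba", "ws", "random_regular", "complete", "path", "star")


def generate_fixture_topology(family: str, params: dict,
                              seed=None) -> nx.Graph:
    """Reproducible graph from a named family.

    ``ba`` (n, m) — preferential attachment seeded with a complete graph
    on m nodes, so the edge count is C(m, 2) + (n - m) * m;
    ``ws`` (n, k, p) — small-world ring rewiring; ``random_regular``
    (n, k); ``complete`` / ``path`` / ``star`` (n).
    """
    if family not in _FAMILIES:
        raise ParameterError(f"unknown topology family {family!r}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    nx_seed = int(rng.integers(2 ** 31 - 1))
    try:
        if family == "ba":
            n, m = int(params["n"]), int(params["m"])
            return nx.barabasi_albert_graph(
                n, m, seed=nx_seed, initial_graph=nx.complete_graph(m))
        if family == "ws":
            return nx.watts_strogatz_graph(
                int(params["n"]), int(params["k"]), float(params["p"]),
                seed=nx_seed)
        if family == "random_regular":
            return nx.random_regular_graph(int(params["k"]),
                                           int(params["n"]), seed=nx_seed)
        if family == "complete":
            return nx.complete_graph(int(params["n"]))
        if family == "path":
            return nx.path_graph(int(params["n"]))
        return nx.star_graph(int(params["n"]) - 1)
    except (nx.NetworkXError, KeyError, ValueError) as err:
        raise ParameterError(f"invalid parameters for {family}: {err}") \
            from None
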