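"""Structural metrics: components, neighborhood function, clustering,
path length, Erdos-Renyi null comparison, modularity scoring."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ParameterError

__all__ = [
    "ComponentSummary", "NeighborhoodFunction", "component_summary",
    "neighborhood_function", "average_clustering", "average_path_length",
    "er_null_metrics", "modularity",
]


@dataclass
class ComponentSummary:
    """Connected-component decomposition with report percentages."""

    sizes: list[tuple[int, int]]  # (n_nodes, n_edges), descending by nodes
    n_nodes: int
    n_edges: int
    giant_node_fraction_pct: float  # rounded to 2 decimals
    giant_edge_fraction_pct: float
    singleton_count: int
    singleton_fraction_pct: float


@dataclass
class NeighborhoodFunction:
    """NF(l): ordered node pairs within l hops, self-pairs included."""

    nf: np.ndarray  # index l = 0..l_max
    n_nodes: int

    @property
    def p(self) -> np.ndarray:
        """Fraction of ordered pairs within l hops, NF(l) / N^2."""
        return self.nf / self.n_nodes**2


def component_summary(g: nx.Graph) -> ComponentSummary:
    """Exact component decomposition with giant/singleton percentages."""
    n, m = g.number_of_nodes(), g.number_of_edges()
    comps = []
    for nodes in nx.connected_components(g):
        sub_edges = sum(1 for u, v in g.edges(nodes) if u in nodes and v in nodes)
        comps.append((len(nodes), sub_edges))
    comps.sort(key=lambda t: (-t[0], -t[1]))
    giant_nodes, giant_edges = comps[0] if comps else (0, 0)
    singletons = sum(1 for size, _ in comps if size == 1)
    pct = lambda num, den: round(100.0 * num / den, 2) if den else 0.0
    return ComponentSummary(
        sizes=comps, n_nodes=n, n_edges=m,
        giant_node_fraction_pct=pct(giant_nodes, n),
        giant_edge_fraction_pct=pct(giant_edges, m),
        singleton_count=singletons,
        singleton_fraction_pct=pct(singletons, n),
    )


def neighborhood_function(g: nx.Graph, l_max: int) -> NeighborhoodFunction:
    """Count ordered pairs (u, v) with d(u, v) <= l by exact BFS.

    NF(0) = N (self-pairs); for disconnected graphs NF saturates at the
    sum of squared component sizes.
    """
    if l_max < 0:
        raise ParameterError(f"l_max must be >= 0, got {l_max}")
    n = g.number_of_nodes()
    hist = np.zeros(l_max + 1, dtype=np.int64)
    for node in g.nodes:
        for dist in nx.single_source_shortest_path_length(g, node).values():
            if dist <= l_max:
                hist[dist] += 1
    return NeighborhoodFunction(nf=np.cumsum(hist), n_nodes=n)


def average_clustering(g: nx.Graph) -> float:
    """Mean local clustering coefficient; degree < 2 nodes contribute 0."""
    if g.number_of_nodes() == 0:
        raise ParameterError("clustering undefined on the empty graph")
    return nx.average_clustering(g, count_zeros=True)


def average_path_length(g: nx.Graph, scope: str = "giant") -> float:
    """Mean shortest-path distance over unordered connected node pairs.

    ``scope="giant"`` restricts to the largest component;
    ``scope="all_connected_pairs"`` averages over every connected pair.
    """
    if g.number_of_nodes() == 0:
        raise ParameterError("path length undefined on the empty graph")
    if scope == "giant":
        giant = max(nx.connected_components(g), key=len)
        components = [g.subgraph(giant)]
    elif scope == "all_connected_pairs":
        components = [g.subgraph(c) for c in nx.connected_components(g)]
    else:
        raise ParameterError(f"unknown scope {scope!r}")
    total, pairs = 0, 0
    for sub in components:
        for node in sub.nodes:
            lengths = nx.single_source_shortest_path_length(sub, node)
            total += sum(lengths.values())
            pairs += len(lengths) - 1
    if pairs == 0:
        raise ParameterError("no connected pairs in scope")
    return total / pairs  # ordered sums cancel: total/pairs == unordered mean


def er_null_metrics(n: int, m: int, seed: int, n_rep: int = 10,
                    compute_path: bool = True) -> dict:
    """Mean clustering and giant-component path length over G(n, m) draws."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not 0 <= m <= n * (n - 1) // 2:
        raise ParameterError(f"m={m} infeasible for n={n}")
    rng = np.random.default_rng(seed)
    clus, paths = [], []
    for _ in range(n_rep):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        clus.append(average_clustering(g))
        if not compute_path:
            paths.append(float("nan"))
            continue
        try:
            paths.append(average_path_length(g, scope="giant"))
        except ParameterError:
            paths.append(float("nan"))
    return {
        "clustering_mean": float(np.mean(clus)),
        "path_length_mean": float(np.nanmean(paths)) if not all(np.isnan(paths)) else float("nan"),
        "clustering_draws": clus,
        "path_length_draws": paths,
        "n_rep": n_rep,
    }


def modularity(g: nx.Graph, partition) -> float:
    """Newman modularity Q = sum_c (e_cc - a_c^2) for a full partition.

    ``partition`` is either a mapping node -> community label or an
    iterable of disjoint node sets covering the graph.
    """
    if isinstance(partition, dict):
        missing = [v for v in g.nodes if v not in partition]
        if missing:
            raise ParameterError(f"partition misses node(s): {missing[:5]}")
        groups: dict = {}
        for node, label in partition.items():
            groups.setdefault(label, set()).add(node)
        communities = list(groups.values())
    else:
        communities = [set(c) for c in partition]
        covered = set().union(*communities) if communities else set()
        if covered != set(g.nodes) or sum(map(len, communities)) != len(covered):
            raise ParameterError("partition must cover all nodes disjointly")
    return float(nx.algorithms.community.modularity(g, communities))
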