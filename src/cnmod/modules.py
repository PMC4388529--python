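"""Module decomposition, modularity null, and hub identification.

The altered-gene network is decomposed with the Girvan–Newman edge-betweenness
algorithm: edges of maximal betweenness are removed iteratively and the
partition taken at the dendrogram cut maximizing Newman modularity

    Q = sum_c [ e_c/m − (d_c/2m)^2 ]

(m edges total, e_c within-module edges, d_c module degree sum).  Whether the
observed modularity exceeds what the degree sequence alone produces is judged
against networks randomized by double edge swaps (pick edges (a,b),(c,d),
rewire to (a,d),(c,b) unless a self-loop or multi-edge would result), which
preserve the exact degree multiset.  The comparison is summarized as the
scaled modularity score (Q_obs − mean Q_null) / sd Q_null and an empirical
p-value.  Hubs are the top 5% of nodes by degree (ties at the cutoff are
included) plus, per module, the node of maximal within-module degree.

The edge-betweenness dendrogram is computed by igraph's C implementation;
nodes and edges are fed to it in sorted order so results are deterministic.
Modularity itself is recomputed here from the formula above.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ModulePartition",
    "ModularityNull",
    "detect_modules",
    "modularity",
    "girvan_newman_cuts",
    "edge_swap_null",
    "find_hubs",
]


@dataclass
class ModulePartition:
    """A disjoint module assignment with per-module summaries and its Q."""

    assignment: dict[str, int]
    modules: pd.DataFrame  # module, n_nodes, n_edges, hub, hub_degree
    q: float


@dataclass
class ModularityNull:
    """Observed modularity against the degree-preserving edge-swap null."""

    q_obs: float
    q_null: np.ndarray
    scaled_score: float  # (q_obs - mean) / sd of the null
    p_emp: float  # fraction of null Q >= observed


def modularity(graph: nx.Graph, assignment: dict[str, int]) -> float:
    """Newman–Girvan modularity of a node->module assignment."""
    missing = set(graph.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment does not cover nodes: {sorted(missing)[:5]}")
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    within: dict[int, int] = {}
    degsum: dict[int, int] = {}
    for u, v in graph.edges():
        if assignment[u] == assignment[v]:
            within[assignment[u]] = within.get(assignment[u], 0) + 1
    for node, deg in graph.degree():
        c = assignment[node]
        degsum[c] = degsum.get(c, 0) + deg
    return float(
        sum(
            within.get(c, 0) / m - (degsum[c] / (2 * m)) ** 2
            for c in degsum
        )
    )


def _to_igraph(graph: nx.Graph) -> tuple[ig.Graph, list[str]]:
    """Deterministic igraph conversion: nodes and edges lexicographically sorted."""
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = sorted(tuple(sorted((index[u], index[v]))) for u, v in graph.edges())
    return ig.Graph(n=len(nodes), edges=edges, directed=False), nodes


def girvan_newman_cuts(graph: nx.Graph) -> list[dict[str, int]]:
    """All partitions along the edge-betweenness dendrogram, coarse to fine.

    Returns one assignment per achievable cluster count, from the connected
    components of the input down to singletons.  Used by
    :func:`detect_modules` (via the modularity-maximizing cut) and by tests
    enumerating the dendrogram exhaustively.
    """
    g, nodes = _to_igraph(graph)
    dendrogram = g.community_edge_betweenness(directed=False)
    n_components = len(g.connected_components())
    cuts = []
    for k in range(n_components, g.vcount() + 1):
        membership = dendrogram.as_clustering(k).membership
        cuts.append({nodes[i]: int(c) for i, c in enumerate(membership)})
    return cuts


def detect_modules(graph) -> ModulePartition:
    """Girvan–Newman module detection at the modularity-maximizing dendrogram cut.

    Accepts an :class:`~cnmod.network.OSNetwork` or a plain undirected graph.
    The returned Q is recomputed from the partition with :func:`modularity`;
    ties between equally good cuts resolve to the coarsest (fewest modules).
    """
    if hasattr(graph, "graph") and isinstance(graph.graph, nx.Graph):
        graph = graph.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if graph.number_of_nodes() == 1:
        node = next(iter(graph.nodes))
        assignment = {node: 0}
    else:
        g, nodes = _to_igraph(graph)
        dendrogram = g.community_edge_betweenness(directed=False)
        membership = dendrogram.as_clustering().membership  # modularity-optimal cut
        assignment = {nodes[i]: int(c) for i, c in enumerate(membership)}

    rows = []
    for module_id in sorted(set(assignment.values())):
        members = sorted(n for n, c in assignment.items() if c == module_id)
        sub = graph.subgraph(members)
        hub, hub_degree = min(
            ((n, d) for n, d in sub.degree()), key=lambda t: (-t[1], t[0])
        )
        rows.append(
            {
                "module": module_id,
                "n_nodes": sub.number_of_nodes(),
                "n_edges": sub.number_of_edges(),
                "hub": hub,
                "hub_degree": hub_degree,
            }
        )
    modules = pd.DataFrame(rows)
    return ModulePartition(
        assignment=assignment, modules=modules, q=modularity(graph, assignment)
    )


def edge_swap_null(
    graph,
    n_networks: int = 1000,
    swaps_per_edge: int = 10,
    seed: int | None = None,
) -> ModularityNull:
    """Modularity of degree-preserving randomizations of the network.

    Each null network applies ``swaps_per_edge * |E|`` attempted double edge
    swaps to a copy of the input and is re-decomposed with
    :func:`detect_modules`.  Degenerate inputs where no legal swap exists
    (fewer than 4 nodes or 2 independent edges) raise with the condition
    named.
    """
    if hasattr(graph, "graph") and isinstance(graph.graph, nx.Graph):
        graph = graph.graph
    m = graph.number_of_edges()
    if graph.number_of_nodes() < 4 or m < 2:
        raise ValueError(
            "no legal double edge swap exists: need >= 4 nodes and >= 2 edges"
        )
    q_obs = detect_modules(graph).q
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_networks)]

    q_null = np.empty(n_networks)
    nswap = swaps_per_edge * m
    for i, s in enumerate(child_seeds):
        null = graph.copy()
        try:
            nx.double_edge_swap(null, nswap=nswap, max_tries=100 * nswap, seed=s)
        except nx.NetworkXAlgorithmError:
            pass  # swap budget exhausted; partially randomized network still valid
        q_null[i] = detect_modules(null).q

    sd = float(q_null.std(ddof=1)) if n_networks > 1 else 0.0
    scaled = (q_obs - float(q_null.mean())) / sd if sd > 0 else float("nan")
    return ModularityNull(
        q_obs=q_obs,
        q_null=q_null,
        scaled_score=scaled,
        p_emp=float((q_null >= q_obs).sum() / n_networks),
    )


def find_hubs(graph, top_fraction: float = 0.05) -> pd.DataFrame:
    """Global hubs: nodes in the top ``top_fraction`` of the degree distribution.

    The cutoff is the k-th largest degree with k = floor(top_fraction * n)
    (at least 1); *all* nodes reaching the cutoff are returned, so ties can
    push the table beyond k rows.  Columns: gene, degree,
    is_copy_number_associated (True for drivers when role attributes are
    present).  Sorted by degree descending, then gene.
    """
    if hasattr(graph, "graph") and isinstance(graph.graph, nx.Graph):
        graph = graph.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    degrees = dict(graph.degree())
    k = max(1, int(np.floor(top_fraction * len(degrees))))
    cutoff = sorted(degrees.values(), reverse=True)[k - 1]
    hubs = sorted(
        ((g, d) for g, d in degrees.items() if d >= cutoff), key=lambda t: (-t[1], t[0])
    )
    roles = nx.get_node_attributes(graph, "role")
    return pd.DataFrame(
        {
            "gene": [g for g, _ in hubs],
            "degree": [d for _, d in hubs],
            "is_copy_number_associated": [roles.get(g, "driver") == "driver" for g, _ in hubs],
        }
    )
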