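"""Altered-gene network assembly on a reference interactome.

Copy-number-associated ("driver") genes are superimposed on an undirected
protein-interaction reference graph.  Two drivers are joined either directly
(interaction path of length 1) or through a non-altered *linker* gene (path
of length 2).  A linker candidate must touch at least two drivers, and is
accepted only if its neighbourhood is enriched for drivers beyond chance:
its driver-neighbour count is compared with its global degree under a
hypergeometric null, BH-adjusted across candidates (q < 0.05).  The final
network is the induced subgraph of the interactome on drivers + accepted
linkers, reduced to its largest connected component.

The global connectedness of the resulting network is assessed against
repeated re-runs of the identical procedure on equally many randomly chosen
interactome genes, with empirical p-values
``sum(connectedness_random > connectedness) / n_permutations`` for node and
edge counts separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .association import bh_fdr

__all__ = [
    "PathInduction",
    "LinkerTest",
    "OSNetwork",
    "ConnectednessNull",
    "induce_paths",
    "linker_pvalue",
    "linker_tests",
    "assemble_network",
    "build_network",
    "connectedness_null",
]

logger = logging.getLogger(__name__)

Interactome = nx.Graph  # simple undirected graph, node labels = gene ids


@dataclass
class PathInduction:
    """Length-1 edges among altered genes and length-2 linker candidates."""

    direct_edges: set[tuple[str, str]]  # sorted pairs, both ends altered
    candidates: dict[str, set[str]]  # non-altered node -> its altered neighbours (>=2)
    altered_in_graph: set[str]
    dropped: set[str]  # altered genes absent from the interactome


@dataclass(frozen=True)
class LinkerTest:
    """Hypergeometric neighbourhood-enrichment test for one linker candidate."""

    gene: str
    global_degree: int
    altered_neighbors: int
    p_hyper: float
    q: float
    accepted: bool

    def __post_init__(self) -> None:
        if self.altered_neighbors > self.global_degree:
            raise ValueError("altered_neighbors cannot exceed global_degree")


@dataclass
class OSNetwork:
    """The assembled altered-gene network (one connected component).

    ``graph`` nodes carry attributes ``role`` ("driver"/"linker"),
    ``alteration`` ("gain"/"loss"/"none") and ``sample_frequency``.
    """

    graph: nx.Graph
    dropped: list[str] = field(default_factory=list)  # genes that found no connection

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_by_role(self, role: str) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["role"] == role)


@dataclass
class ConnectednessNull:
    """Observed vs random-gene-set network size, with empirical p-values."""

    observed_nodes: int
    observed_edges: int
    null_nodes: np.ndarray
    null_edges: np.ndarray
    p_nodes: float
    p_edges: float


def induce_paths(interactome: nx.Graph, altered: set[str]) -> PathInduction:
    """Identify all interaction paths of length 1 or 2 among altered genes.

    Direct edges have both ends altered.  A linker candidate is a non-altered
    interactome node adjacent to at least two altered genes; the same driver
    pair may be bridged by several linkers.  Altered genes absent from the
    interactome are dropped (count logged).
    """
    present = {g for g in altered if g in interactome}
    dropped = set(altered) - present
    if dropped:
        logger.info("induce_paths: %d altered genes absent from interactome", len(dropped))
    if not present:
        raise ValueError("no altered genes present in the interactome")

    direct = {
        tuple(sorted((u, v)))
        for u, v in interactome.edges()
        if u in present and v in present
    }
    candidates: dict[str, set[str]] = {}
    for g in present:
        for nb in interactome.neighbors(g):
            if nb in present:
                continue
            candidates.setdefault(nb, set()).add(g)
    candidates = {n: s for n, s in candidates.items() if len(s) >= 2}
    return PathInduction(
        direct_edges=direct, candidates=candidates,
        altered_in_graph=present, dropped=dropped,
    )


def linker_pvalue(n_population: int, n_altered: int, degree: int, observed: int) -> float:
    """Upper-tail hypergeometric probability P(X >= observed).

    Drawing ``degree`` neighbours from a population of ``n_population`` genes
    of which ``n_altered`` are altered, the chance of seeing at least
    ``observed`` altered neighbours.
    """
    if degree == 0:
        raise ValueError("degenerate candidate: global degree 0")
    if observed > degree or n_altered > n_population:
        raise ValueError("inconsistent hypergeometric parameters")
    return float(hypergeom.sf(observed - 1, n_population, n_altered, degree))


def linker_tests(
    induction: PathInduction,
    interactome: nx.Graph,
    fdr_threshold: float = 0.05,
) -> list[LinkerTest]:
    """Test every linker candidate's neighbourhood for driver enrichment.

    Population = all interactome genes minus the candidate itself (a node is
    never its own neighbour); successes = altered genes present in the
    interactome; draws = the candidate's global degree.  BH-FDR across all
    candidates; accepted iff q < ``fdr_threshold``.
    """
    cands = sorted(induction.candidates)
    if not cands:
        return []
    n_pop = interactome.number_of_nodes() - 1
    m = len(induction.altered_in_graph)
    degrees = np.array([interactome.degree(c) for c in cands])
    observed = np.array([len(induction.candidates[c]) for c in cands])
    p = hypergeom.sf(observed - 1, n_pop, m, degrees)
    q = bh_fdr(p)
    return [
        LinkerTest(
            gene=c,
            global_degree=int(d),
            altered_neighbors=int(o),
            p_hyper=float(pi),
            q=float(qi),
            accepted=bool(qi < fdr_threshold),
        )
        for c, d, o, pi, qi in zip(cands, degrees, observed, p, q)
    ]


def assemble_network(
    induction: PathInduction,
    linkers: list[LinkerTest],
    interactome: nx.Graph,
    frequencies: pd.DataFrame | None = None,
) -> OSNetwork:
    """Join drivers and accepted linkers into one connected component.

    Node set: altered genes incident to a direct edge or adjacent to an
    accepted linker, plus the accepted linkers.  Edge set: *all* interactome
    edges among those nodes (induced subgraph).  Only the largest connected
    component is kept; genes that found no connection are reported in
    ``dropped``, not silently discarded.

    ``frequencies`` (index gene, columns gain_freq / loss_freq, from
    :func:`cnmod.segments.recurrence_filter`) fills the node attributes: a
    driver's alteration is its majority direction (ties -> "gain") and its
    sample_frequency that direction's frequency.
    """
    accepted = {t.gene for t in linkers if t.accepted}
    keep: set[str] = set(accepted)
    for u, v in induction.direct_edges:
        keep.add(u)
        keep.add(v)
    for linker in accepted:
        keep |= induction.candidates[linker]

    sub = interactome.subgraph(keep).copy()
    if sub.number_of_nodes() == 0:
        raise ValueError("empty network: no connected altered genes or accepted linkers")
    components = sorted(nx.connected_components(sub), key=lambda c: (-len(c), sorted(c)))
    giant = components[0]
    dropped = sorted((induction.altered_in_graph | accepted) - giant)
    g = sub.subgraph(giant).copy()

    for node in g.nodes:
        if node in accepted and node not in induction.altered_in_graph:
            g.nodes[node].update(role="linker", alteration="none", sample_frequency=0.0)
            continue
        alteration, freq = "gain", 0.0
        if frequencies is not None and node in frequencies.index:
            gf = float(frequencies.loc[node, "gain_freq"])
            lf = float(frequencies.loc[node, "loss_freq"])
            alteration = "loss" if lf > gf else "gain"  # ties -> gain
            freq = max(gf, lf)
        g.nodes[node].update(role="driver", alteration=alteration, sample_frequency=freq)
    return OSNetwork(graph=g, dropped=dropped)


def build_network(
    interactome: nx.Graph,
    altered: set[str],
    frequencies: pd.DataFrame | None = None,
    linker_fdr: float = 0.05,
) -> tuple[OSNetwork, list[LinkerTest]]:
    """Full path induction -> linker testing -> assembly in one call."""
    induction = induce_paths(interactome, altered)
    tests = linker_tests(induction, interactome, fdr_threshold=linker_fdr)
    net = assemble_network(induction, tests, interactome, frequencies=frequencies)
    return net, tests


def connectedness_null(
    interactome: nx.Graph,
    n_altered: int,
    observed_nodes: int,
    observed_edges: int,
    n_perm: int = 1000,
    seed: int | None = None,
    linker_fdr: float = 0.05,
) -> ConnectednessNull:
    """Connectedness of the observed network vs random gene sets of equal size.

    Each iteration draws ``n_altered`` interactome genes uniformly without
    replacement and runs the identical pipeline (path induction, linker
    testing at the same FDR, assembly); iterations yielding no network count
    as size 0.  Empirical p = fraction of random networks strictly larger
    than the observed one, separately for nodes and edges.
    """
    if n_altered > interactome.number_of_nodes():
        raise ValueError("n_altered exceeds interactome size")
    rng = np.random.default_rng(seed)
    genes = sorted(interactome.nodes)
    null_nodes = np.zeros(n_perm, dtype=int)
    null_edges = np.zeros(n_perm, dtype=int)
    for i in range(n_perm):
        picked = set(rng.choice(genes, size=n_altered, replace=False))
        try:
            net, _ = build_network(interactome, picked, linker_fdr=linker_fdr)
        except ValueError:
            continue  # no connected network from this draw: size 0
        null_nodes[i] = net.n_nodes
        null_edges[i] = net.n_edges
    return ConnectednessNull(
        observed_nodes=observed_nodes,
        observed_edges=observed_edges,
        null_nodes=null_nodes,
        null_edges=null_edges,
        p_nodes=float((null_nodes > observed_nodes).sum() / n_perm),
        p_edges=float((null_edges > observed_edges).sum() / n_perm),
    )
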