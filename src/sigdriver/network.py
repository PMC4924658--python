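"""Seed-expanded interaction networks, cleaning, Steiner reduction, topology.

Differentially expressed proteins (or robust signature genes) act as *root*
seeds that fish their interaction partners out of one or more edge tables.
The expanded network is cleaned (self-loops dropped, isolated nodes deleted,
largest connected component kept), optionally reduced to an approximate
Steiner minimal tree over the roots, and every node is scored by degree k_n
and the clustering coefficient

    CC = 2 * e_n / (k_n * (k_n - 1))

with e_n the number of edges among the node's neighbors (CC = 0 by convention
when k_n < 2). Roots are ranked by descending degree with ascending CC as the
tie-break: a high-degree, low-CC root is a hub whose partners do not talk to
each other — the signature of a driver bottleneck.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from networkx.algorithms.approximation import steiner_tree as _nx_steiner

from .exceptions import NetworkError, ParseError


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------

@dataclass
class InteractionSet:
    """Undirected, de-duplicated interaction edges with source tags.

    ``graph`` holds one edge per unordered pair; the ``sources`` edge
    attribute is the set of files (or database tags) the edge came from.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    discarded_self_loops: int = 0

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def add_edge(self, a: str, b: str, source: str) -> None:
        if a == b:
            self.discarded_self_loops += 1
            return
        if self.graph.has_edge(a, b):
            self.graph[a][b]["sources"].add(source)
        else:
            self.graph.add_edge(a, b, sources={source})

    def edge_frame(self) -> pd.DataFrame:
        rows = [(min(a, b), max(a, b), ",".join(sorted(d["sources"])))
                for a, b, d in self.graph.edges(data=True)]
        return pd.DataFrame(sorted(rows),
                            columns=["node_a", "node_b", "sources"])


def load_interactions(paths: Sequence) -> InteractionSet:
    """Union of 2-column TSV and SIF edge files into one interaction set.

    A 2-column line is an edge pair; a line with 3+ columns is SIF
    (nodeA, interaction type, one or more targets). Self-loops are dropped
    and tallied; duplicate undirected edges merge their source tags.
    Malformed (single-column) lines raise :class:`ParseError` with the line
    number.
    """
    out = InteractionSet()
    for path in paths:
        tag = Path(str(path)).name
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) == 1:
                    cols = line.split()
                if len(cols) == 2:
                    out.add_edge(cols[0], cols[1], tag)
                elif len(cols) >= 3:
                    a = cols[0]
                    for b in cols[2:]:
                        out.add_edge(a, b, tag)
                else:
                    raise ParseError(str(path), lineno,
                                     f"expected >= 2 columns, got {len(cols)}")
    return out


def interactions_from_frame(edges: pd.DataFrame, source: str = "table"
                            ) -> InteractionSet:
    """Build an InteractionSet from a (node_a, [interaction,] node_b) frame."""
    out = InteractionSet()
    cols = list(edges.columns)
    a_col, b_col = cols[0], cols[-1]
    for a, b in zip(edges[a_col], edges[b_col]):
        out.add_edge(str(a), str(b), source)
    return out


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass
class GeneNetwork:
    """Undirected network with root/interactor roles.

    ``graph`` nodes carry a ``role`` attribute (``root`` for seeds,
    ``interactor`` otherwise); ``missing_seeds`` reports requested seeds that
    were absent from the interaction universe.
    """

    graph: nx.Graph
    missing_seeds: list[str] = field(default_factory=list)

    @property
    def roots(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d.get("role") == "root")

    @property
    def interactors(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True)
                      if d.get("role") != "root")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def write_sif(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in sorted((min(a, b), max(a, b))
                               for a, b in self.graph.edges()):
                fh.write(f"{a}\tpp\t{b}\n")


def build_seed_network(interactions: InteractionSet, seeds: Sequence[str],
                       order: int = 1, induced: bool = True) -> GeneNetwork:
    """Expand seeds by ``order`` neighborhood hops in the interaction universe.

    The node set is every seed found in the universe plus all nodes within
    ``order`` hops of any seed. With ``induced`` (default) all universe edges
    among included nodes are kept; with ``induced=False`` only the expansion
    edges (star edges along the hop frontier) are kept. Seeds missing from
    the universe are omitted and listed in ``missing_seeds``; if none are
    present a :class:`NetworkError` is raised.
    """
    if order not in (1, 2):
        raise NetworkError("neighborhood order must be 1 or 2")
    universe = interactions.graph
    seeds = list(dict.fromkeys(seeds))
    present = [s for s in seeds if s in universe]
    missing = [s for s in seeds if s not in universe]
    if not present:
        raise NetworkError("no seed is present in the interaction universe")

    nodes = set(present)
    frontier = set(present)
    star_edges = set()
    for _ in range(order):
        nxt = set()
        for u in frontier:
            for v in universe.neighbors(u):
                if v not in nodes:
                    nxt.add(v)
                star_edges.add((min(u, v), max(u, v)))
        nodes |= nxt
        frontier = nxt

    g = nx.Graph()
    g.add_nodes_from(nodes)
    if induced:
        g.add_edges_from(universe.subgraph(nodes).edges())
    else:
        g.add_edges_from(star_edges)
    for n in g.nodes:
        g.nodes[n]["role"] = "root" if n in set(present) else "interactor"
    return GeneNetwork(graph=g, missing_seeds=missing)


def clean_network(network: GeneNetwork) -> GeneNetwork:
    """Drop self-loops and isolated nodes, keep the largest component.

    A size tie between components is broken in favor of the component
    containing the lexicographically smallest node id. Cleaning an
    already-clean network is a no-op; an empty result raises
    :class:`NetworkError`.
    """
    g = network.graph.copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_nodes() == 0:
        raise NetworkError("network is empty after cleaning")
    components = sorted(nx.connected_components(g),
                        key=lambda c: (-len(c), min(c)))
    keep = components[0]
    g = g.subgraph(keep).copy()
    return GeneNetwork(graph=g, missing_seeds=list(network.missing_seeds))


# ---------------------------------------------------------------------------
# Steiner reduction
# ---------------------------------------------------------------------------

@dataclass
class SteinerResult:
    """Approximate Steiner minimal tree over a terminal set.

    ``cost`` is the edge count (edges are unweighted), which equals
    node count - 1 for a tree.
    """

    tree: nx.Graph
    terminals: list[str]
    cost: int

    @property
    def nodes(self) -> list[str]:
        return sorted(self.tree.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted((min(a, b), max(a, b)) for a, b in self.tree.edges)


def steiner_tree(network: GeneNetwork, terminals: Sequence[str]
                 ) -> SteinerResult:
    """Metric-closure MST approximation of the Steiner minimal tree.

    Shortest paths between terminals define a complete metric closure; its
    minimum spanning tree is expanded back to original edges and non-terminal
    leaves are pruned. The result spans every terminal. Terminals absent from
    the network raise :class:`NetworkError` listing the offenders.
    """
    terminals = list(dict.fromkeys(terminals))
    missing = [t for t in terminals if t not in network.graph]
    if missing:
        raise NetworkError(f"terminals not in network: {sorted(missing)}")
    if not terminals:
        raise NetworkError("empty terminal set")
    if len(terminals) == 1:
        tree = nx.Graph()
        tree.add_node(terminals[0])
        return SteinerResult(tree=tree, terminals=terminals, cost=0)

    approx = _nx_steiner(network.graph, terminals, method="kou")
    tree = nx.minimum_spanning_tree(approx)  # guard: guarantee acyclicity
    # prune non-terminal leaves until fixed point
    tset = set(terminals)
    changed = True
    while changed:
        changed = False
        for leaf in [n for n in tree.nodes
                     if tree.degree(n) <= 1 and n not in tset]:
            tree.remove_node(leaf)
            changed = True
    return SteinerResult(tree=tree, terminals=terminals,
                         cost=tree.number_of_edges())


# ---------------------------------------------------------------------------
# topology & ranking
# ---------------------------------------------------------------------------

def node_topology(network: GeneNetwork) -> pd.DataFrame:
    """Per-node degree k_n, neighbor-edge count e_n and clustering CC.

    CC = 2 e_n / (k_n (k_n - 1)) for k_n >= 2, else 0.
    """
    g = network.graph
    rows = []
    for n in sorted(g.nodes):
        nbrs = list(g.neighbors(n))
        k = len(nbrs)
        e = g.subgraph(nbrs).number_of_edges()
        cc = 2.0 * e / (k * (k - 1)) if k >= 2 else 0.0
        rows.append((n, g.nodes[n].get("role", "interactor"), k, e, cc))
    return pd.DataFrame(rows, columns=["node", "role", "k_n", "e_n", "cc"]
                        ).set_index("node")


def rank_roots(network: GeneNetwork, roots: Sequence[str] | None = None
               ) -> pd.DataFrame:
    """Rank root proteins by descending degree, then ascending CC, then id.

    Roots absent from the network are omitted; their ids are recorded in the
    returned frame's ``attrs["missing_roots"]``.
    """
    if roots is None:
        roots = network.roots
    present = [r for r in dict.fromkeys(roots) if r in network.graph]
    missing = sorted(set(roots) - set(present))
    topo = node_topology(network)
    table = topo.loc[present, ["k_n", "e_n", "cc"]].copy()
    table = table.sort_values(by=["k_n", "cc"], ascending=[False, True],
                              kind="stable")
    # final lexicographic tie-break on node id
    table["_id"] = table.index
    table = table.sort_values(by=["k_n", "cc", "_id"],
                              ascending=[False, True, True]).drop(columns="_id")
    table.insert(0, "rank", range(1, len(table) + 1))
    table.attrs["missing_roots"] = missing
    return table


def match_signatures_to_atlas(signatures: Sequence[str],
                              atlas: InteractionSet,
                              order: int = 1) -> GeneNetwork:
    """Expand signature genes against an interaction atlas and clean.

    Equivalent to seeding the atlas with the signature list, taking the
    order-``order`` induced neighborhood, and keeping the largest component.
    """
    return clean_network(build_seed_network(atlas, signatures, order=order))
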