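"""Interaction loading, seed expansion, cleaning, Steiner, topology, ranking."""

import itertools

import networkx as nx
import numpy as np
import pytest

from sigdriver import (build_seed_network, clean_network,
                       interactions_from_frame, load_interactions,
                       match_signatures_to_atlas, node_topology, rank_roots,
                       simulate_ppi, steiner_tree)
from sigdriver.exceptions import NetworkError, ParseError
from sigdriver.network import GeneNetwork


def _write(tmp_path, name, lines):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


# -- loading -----------------------------------------------------------------

def test_union_merges_source_tags(tmp_path):
    f1 = _write(tmp_path, "db1.tsv", ["A\tB"])
    f2 = _write(tmp_path, "db2.sif", ["A\tpp\tB"])
    iset = load_interactions([f1, f2])
    assert iset.n_edges == 1
    assert iset.graph["A"]["B"]["sources"] == {"db1.tsv", "db2.sif"}


def test_self_loops_dropped_and_tallied(tmp_path):
    f = _write(tmp_path, "db.tsv", ["A\tA", "A\tB"])
    iset = load_interactions([f])
    assert iset.n_edges == 1
    assert iset.discarded_self_loops == 1


def test_malformed_line_reports_position(tmp_path):
    f = _write(tmp_path, "bad.tsv", ["A\tB", "LONELY"])
    with pytest.raises(ParseError) as err:
        load_interactions([f])
    assert err.value.lineno == 2


def test_load_is_partition_invariant(tmp_path):
    edges, _ = simulate_ppi(120, 3, 2, seed=1)
    lines = [f"{a}\tpp\t{b}" for a, b in zip(edges["node_a"], edges["node_b"])]
    whole = load_interactions([_write(tmp_path, "all.sif", lines)])
    thirds = [lines[i::3] for i in range(3)]
    parts = load_interactions([
        _write(tmp_path, f"part{i}.sif", chunk)
        for i, chunk in enumerate(thirds)])
    same_edges = nx.utils.graphs_equal(
        nx.Graph(whole.graph.edges()), nx.Graph(parts.graph.edges()))
    assert same_edges


# -- seed expansion -----------------------------------------------------------

def _iset(edge_list):
    out = interactions_from_frame(
        __import__("pandas").DataFrame(edge_list, columns=["node_a", "node_b"]))
    return out


def test_star_expansion_around_single_seed():
    iset = _iset([("H", "a"), ("H", "b"), ("H", "c"), ("x", "y")])
    net = build_seed_network(iset, ["H"], order=1)
    assert set(net.graph.nodes) == {"H", "a", "b", "c"}
    assert net.n_edges == 3
    assert net.roots == ["H"]


def test_missing_seed_is_reported_not_fatal():
    iset = _iset([("H", "a")])
    net = build_seed_network(iset, ["H", "GHOST"], order=1)
    assert net.missing_seeds == ["GHOST"]
    assert "GHOST" not in net.graph


def test_all_seeds_missing_is_an_error():
    iset = _iset([("A", "B")])
    with pytest.raises(NetworkError):
        build_seed_network(iset, ["GHOST"], order=1)


def test_expansion_matches_adjacency_union_oracle():
    edges, truth = simulate_ppi(2000, 17, 2, seed=2)
    iset = interactions_from_frame(edges)
    net = build_seed_network(iset, truth.hub_seeds, order=1)
    # brute-force: seeds plus every adjacency-list entry
    adjacency = {}
    for a, b in zip(edges["node_a"], edges["node_b"]):
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    expected = set(truth.hub_seeds)
    for s in truth.hub_seeds:
        expected |= adjacency.get(s, set())
    assert set(net.graph.nodes) == expected


def test_order_two_reaches_second_neighbors():
    iset = _iset([("H", "a"), ("a", "b"), ("b", "c")])
    net1 = build_seed_network(iset, ["H"], order=1)
    net2 = build_seed_network(iset, ["H"], order=2)
    assert set(net1.graph.nodes) == {"H", "a"}
    assert set(net2.graph.nodes) == {"H", "a", "b"}


# -- cleaning -----------------------------------------------------------------

def test_largest_component_kept():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"),
                      ("x", "y"), ("y", "z")])
    cleaned = clean_network(GeneNetwork(graph=g))
    assert set(cleaned.graph.nodes) == {"a", "b", "c", "d", "e"}


def test_component_tie_broken_lexicographically():
    g = nx.Graph()
    g.add_edges_from([("b", "c"), ("a", "d")])  # two 2-node components
    cleaned = clean_network(GeneNetwork(graph=g))
    assert set(cleaned.graph.nodes) == {"a", "d"}


def test_cleaned_graph_is_connected_by_bfs_oracle():
    edges, truth = simulate_ppi(300, 4, 1, seed=5)
    net = build_seed_network(interactions_from_frame(edges), truth.hub_seeds)
    cleaned = clean_network(net)
    nodes = list(cleaned.graph.nodes)
    seen = {nodes[0]}
    frontier = [nodes[0]]
    while frontier:
        nxt = []
        for u in frontier:
            for v in cleaned.graph.neighbors(u):
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    assert seen == set(nodes)
    assert nx.number_of_selfloops(cleaned.graph) == 0
    assert not list(nx.isolates(cleaned.graph))


def test_cleaning_is_idempotent():
    edges, truth = simulate_ppi(200, 3, 1, seed=6)
    net = clean_network(
        build_seed_network(interactions_from_frame(edges), truth.hub_seeds))
    again = clean_network(net)
    assert nx.utils.graphs_equal(net.graph, again.graph)


def test_empty_after_cleaning_is_an_error():
    g = nx.Graph()
    g.add_edge("a", "a")
    with pytest.raises(NetworkError):
        clean_network(GeneNetwork(graph=g))


# -- Steiner ------------------------------------------------------------------

def test_path_graph_endpoints_span_whole_path():
    g = nx.path_graph(["a", "b", "c", "d", "e"])
    res = steiner_tree(GeneNetwork(graph=g), ["a", "e"])
    assert res.cost == 4
    assert set(res.nodes) == {"a", "b", "c", "d", "e"}


def test_single_terminal_is_degenerate_tree():
    g = nx.path_graph(["a", "b", "c"])
    res = steiner_tree(GeneNetwork(graph=g), ["b"])
    assert res.cost == 0
    assert res.nodes == ["b"]


def test_unknown_terminal_listed_in_error():
    g = nx.path_graph(["a", "b"])
    with pytest.raises(NetworkError, match="GHOST"):
        steiner_tree(GeneNetwork(graph=g), ["a", "GHOST"])


def _exhaustive_steiner_cost(g, terminals):
    """Minimum edges of any connected subgraph spanning the terminals."""
    others = [n for n in g.nodes if n not in set(terminals)]
    best = None
    for r in range(len(others) + 1):
        for extra in itertools.combinations(others, r):
            nodes = set(terminals) | set(extra)
            sub = g.subgraph(nodes)
            if nx.is_connected(sub):
                best = len(nodes) - 1
                break
        if best is not None:
            break
    return best


def test_approximation_within_kmb_bound_on_small_graphs():
    rng = np.random.default_rng(42)
    checked = 0
    while checked < 50:
        n = int(rng.integers(6, 11))
        p = float(rng.uniform(0.25, 0.6))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        if not nx.is_connected(g):
            continue
        terminals = sorted(rng.choice(n, size=4, replace=False).tolist())
        opt = _exhaustive_steiner_cost(g, terminals)
        res = steiner_tree(GeneNetwork(graph=g), terminals)
        assert nx.is_tree(res.tree)
        assert set(terminals) <= set(res.tree.nodes)
        assert res.cost <= 2 * (1 - 1 / 4) * opt
        # sanity: at least the farthest terminal pair's distance
        far = max(nx.shortest_path_length(g, a, b)
                  for a, b in itertools.combinations(terminals, 2))
        assert res.cost >= far
        checked += 1


# -- topology -----------------------------------------------------------------

def test_star_hub_has_zero_clustering():
    g = nx.star_graph(843)  # hub 0 with 843 mutually unconnected partners
    topo = node_topology(GeneNetwork(graph=g))
    assert topo.loc[0, "k_n"] == 843
    assert topo.loc[0, "e_n"] == 0
    assert topo.loc[0, "cc"] == 0.0


def test_triangle_vertex_has_unit_clustering():
    g = nx.complete_graph(3)
    topo = node_topology(GeneNetwork(graph=g))
    assert (topo["k_n"] == 2).all()
    assert (topo["e_n"] == 1).all()
    assert (topo["cc"] == 1.0).all()


def test_topology_matches_brute_force_enumeration():
    g = nx.gnp_random_graph(200, 0.05, seed=7)
    topo = node_topology(GeneNetwork(graph=g))
    for n in g.nodes:
        nbrs = list(g.neighbors(n))
        k = len(nbrs)
        e = sum(1 for a, b in itertools.combinations(nbrs, 2)
                if g.has_edge(a, b))
        cc = 2 * e / (k * (k - 1)) if k >= 2 else 0.0
        assert topo.loc[n, "k_n"] == k
        assert topo.loc[n, "e_n"] == e
        assert abs(topo.loc[n, "cc"] - cc) < 1e-12


def test_clustering_bounds_and_clique_law():
    for seed in range(100):
        g = nx.gnp_random_graph(40, 0.15, seed=seed)
        topo = node_topology(GeneNetwork(graph=g))
        assert ((topo["cc"] >= 0) & (topo["cc"] <= 1)).all()
        assert (topo["e_n"] <= topo["k_n"] * (topo["k_n"] - 1) / 2).all()
    clique = nx.complete_graph(6)
    assert (node_topology(GeneNetwork(graph=clique))["cc"] == 1.0).all()


# -- root ranking -------------------------------------------------------------

def _role_net(edges, roots):
    g = nx.Graph(edges)
    for n in g.nodes:
        g.nodes[n]["role"] = "root" if n in roots else "interactor"
    return GeneNetwork(graph=g)


def test_degree_dominates_ranking():
    edges = [("A", f"i{k}") for k in range(10)] + [("B", "i0"), ("B", "i1"),
                                                   ("B", "i2"), ("i1", "i2")]
    net = _role_net(edges, {"A", "B"})
    ranking = rank_roots(net)
    assert list(ranking.index) == ["A", "B"]


def test_lower_clustering_wins_degree_ties():
    # C and D both degree 2; D sits in a triangle (CC=1), C does not (CC=0)
    edges = [("C", "x"), ("C", "y"), ("D", "u"), ("D", "v"), ("u", "v"),
             ("x", "u")]
    net = _role_net(edges, {"C", "D"})
    ranking = rank_roots(net)
    assert list(ranking.index) == ["C", "D"]
    assert ranking.loc["C", "cc"] == 0.0


def test_missing_roots_reported():
    net = _role_net([("A", "b")], {"A"})
    ranking = rank_roots(net, roots=["A", "GONE"])
    assert ranking.attrs["missing_roots"] == ["GONE"]
    assert list(ranking.index) == ["A"]


def test_planted_top_hub_ranks_first():
    edges, truth = simulate_ppi(1000, 17, 2, seed=8)
    iset = interactions_from_frame(edges)
    net = clean_network(build_seed_network(iset, truth.hub_seeds, order=1))
    ranking = rank_roots(net)
    degrees = {h: iset.graph.degree(h) for h in truth.hub_seeds}
    assert ranking.index[0] == max(sorted(degrees), key=degrees.get)


# -- atlas matching -----------------------------------------------------------

def test_signatures_disjoint_from_atlas_raise():
    iset = _iset([("A", "B")])
    with pytest.raises(NetworkError):
        match_signatures_to_atlas(["Z1", "Z2"], iset)


def test_single_signature_gene_expands_to_partners():
    iset = _iset([("S", "p1"), ("S", "p2"), ("q", "r")])
    net = match_signatures_to_atlas(["S"], iset)
    assert set(net.graph.nodes) == {"S", "p1", "p2"}
    assert net.roots == ["S"]


def test_atlas_match_equals_fresh_recomputation(small_scenario):
    _, truth = small_scenario
    edges, net_truth = simulate_ppi(300, 5, 2, seed=9,
                                    node_ids=[f"G{i:05d}" for i in range(300)])
    iset = interactions_from_frame(edges)
    signatures = sorted(truth.de_genes)[:10]
    net = match_signatures_to_atlas(signatures, iset)
    oracle = clean_network(build_seed_network(iset, signatures, order=1))
    assert set(net.graph.nodes) == set(oracle.graph.nodes)
    assert set(map(frozenset, net.graph.edges)) \
        == set(map(frozenset, oracle.graph.edges))
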