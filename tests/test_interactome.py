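"""Interactome building: parsing, filtering, expansion, distances, subnets."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tapprio.interactome import (
    InteractionRecord,
    build_network,
    build_network_from_records,
    candidate_network_features,
    expand_complexes,
    extract_subnetwork,
    filter_predicted,
    network_density,
    network_stats,
    read_interactions,
    shortest_distances,
)
from tapprio.registry import FormatError, ProteinRef


def _rec(ids, kind="binary", method="two hybrid"):
    return InteractionRecord([ProteinRef(i) for i in ids], kind, method)


# --- parsing ----------------------------------------------------------------


def test_read_interactions(tmp_path):
    p = tmp_path / "mitab.tsv"
    p.write_text(
        "# header\n"
        "r1\tp1;p2\tbinary\ttwo hybrid\tdbX\n"
        "r2\tp1;p2;p3\tcomplex\taffinity chromatography\tdbX\n"
        "r3\tp9\tbinary\ttwo hybrid\tdbX\n"  # skipped: <2 members
    )
    records = read_interactions(p)
    assert [r.kind for r in records] == ["binary", "complex"]
    assert [m.id for m in records[1].members] == ["p1", "p2", "p3"]


def test_read_interactions_malformed_line_reports_lineno(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("r1\tp1;p2\n")
    with pytest.raises(FormatError, match="1"):
        read_interactions(p)


def test_two_member_complex_demoted_to_binary():
    rec = _rec(["a", "b"], kind="complex")
    assert rec.kind == "binary"


# --- filtering --------------------------------------------------------------


@pytest.mark.parametrize(
    "method,kept",
    [
        ("predicted by homology", False),
        ("two hybrid", True),
        ("Interologs Mapping", False),
        ("CONFIRMATIONAL TEXT MINING step", False),
        ("pull down", True),
    ],
)
def test_filter_predicted_case_insensitive_substring(method, kept):
    out = filter_predicted([_rec(["a", "b"], method=method)])
    assert bool(out) is kept


def test_filter_preserves_order():
    recs = [_rec(["a", "b"]), _rec(["c", "d"], method="predicted"), _rec(["e", "f"])]
    out = filter_predicted(recs)
    assert [r.members[0].id for r in out] == ["a", "e"]


# --- expansion --------------------------------------------------------------


def test_matrix_expansion_triangle():
    pairs = expand_complexes([_rec(["x", "y", "z"], kind="complex")])
    assert set(pairs) == {
        frozenset(p) for p in [("x", "y"), ("x", "z"), ("y", "z")]
    }
    assert all(ev.has_complex_evidence for ev in pairs.values())


def test_provenance_merged_across_records():
    pairs = expand_complexes(
        [_rec(["a", "b"]), _rec(["a", "b", "c"], kind="complex")]
    )
    ev = pairs[frozenset(("a", "b"))]
    assert ev.has_binary_evidence and ev.has_complex_evidence


def test_duplicate_members_do_not_self_pair():
    rec = InteractionRecord(
        [ProteinRef("a"), ProteinRef("a"), ProteinRef("b")], "complex"
    )
    pairs = expand_complexes([rec])
    assert set(pairs) == {frozenset(("a", "b"))}


@settings(max_examples=30, deadline=None, derandomize=True)
@given(k=st.integers(min_value=3, max_value=12))
def test_expansion_size_is_k_choose_2(k):
    members = [f"m{i}" for i in range(k)]
    pairs = expand_complexes([_rec(members, kind="complex")])
    assert len(pairs) == k * (k - 1) // 2


# --- graph assembly and stats ----------------------------------------------


def test_build_network_dedup_and_empty():
    pairs = expand_complexes([_rec(["a", "b"]), _rec(["a", "b"])])
    g = build_network(pairs)
    assert g.number_of_edges() == 1
    assert build_network({}).number_of_nodes() == 0


def test_density_complete_graph_and_printed_sizes():
    g = build_network(expand_complexes([_rec(list("abcd"), kind="complex")]))
    assert network_stats(g)["density"] == pytest.approx(1.0)
    # published subnetwork size: 4,009 proteins, 290,496 interactions -> 3.6%
    assert round(100 * network_density(4009, 290496), 1) == 3.6


def test_components_and_degrees():
    g = build_network_from_records(
        [_rec(["a", "b"]), _rec(["b", "c"])], drop_predicted=False
    )
    g.add_node("d")
    stats = network_stats(g)
    assert {frozenset(c) for c in stats["components"]} == {
        frozenset("abc"),
        frozenset("d"),
    }
    assert stats["degrees"]["b"] == 2


# --- shortest distances -----------------------------------------------------


def test_bfs_path_and_two_sources():
    g = nx.path_graph(["a", "b", "c"])
    d = shortest_distances(g, ["a"])
    assert d["c"].distance == 2 and d["a"].distance == 0
    star = nx.star_graph(3)
    res = shortest_distances(star, [1, 2])
    assert res[0].distance == 1 and res[0].n_sources_at_min == 2
    assert res[0].sources_at_distance_1 == {1, 2}
    # a leaf sees both sources at distance 2 through the center
    assert res[3].distance == 2 and res[3].n_sources_at_min == 2


def test_unreachable_and_absent_sources_are_undefined():
    g = nx.Graph([("a", "b")])
    g.add_node("island")
    d = shortest_distances(g, ["a"])
    assert "island" not in d
    assert shortest_distances(g, ["ghost"]) == {}
    assert shortest_distances(g, []) == {}


def _floyd_warshall(nodes, edges):
    inf = float("inf")
    dist = {u: {v: (0 if u == v else inf) for v in nodes} for u in nodes}
    for u, v in edges:
        dist[u][v] = dist[v][u] = 1
    for w in nodes:
        for u in nodes:
            for v in nodes:
                if dist[u][w] + dist[w][v] < dist[u][v]:
                    dist[u][v] = dist[u][w] + dist[w][v]
    return dist


@pytest.mark.parametrize("trial", range(0, 200, 10))
def test_bfs_agrees_with_floyd_warshall_oracle(trial):
    """20 random graphs per run of this module x 10 in test_acceptance."""
    import random

    rng = random.Random(trial)
    for rep in range(20):
        n = rng.randint(2, 20)
        nodes = [f"n{i}" for i in range(n)]
        edges = [
            (a, b)
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.25
        ]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        sources = rng.sample(nodes, rng.randint(1, min(3, n)))
        oracle = _floyd_warshall(nodes, edges)
        got = shortest_distances(g, sources)
        for v in nodes:
            best = min(oracle[s][v] for s in sources)
            if best == float("inf"):
                assert v not in got
            else:
                assert got[v].distance == best
                assert got[v].n_sources_at_min == sum(
                    1 for s in sources if oracle[s][v] == best
                )


# --- shortest-path subnetwork ----------------------------------------------


def test_subnetwork_single_geodesic():
    g = nx.path_graph(["a", "x", "b"])
    sub = extract_subnetwork(g, ["a"], ["b"])
    assert set(sub.nodes) == {"a", "x", "b"} and sub.number_of_edges() == 2


def test_subnetwork_keeps_all_geodesics():
    g = nx.Graph([("a", "x"), ("x", "b"), ("a", "y"), ("y", "b")])
    sub = extract_subnetwork(g, ["a"], ["b"])
    assert {"x", "y"} <= set(sub.nodes)


def test_subnetwork_shorter_geodesic_wins():
    g = nx.Graph([("a", "x"), ("x", "y"), ("y", "b"), ("a", "z"), ("z", "b")])
    sub = extract_subnetwork(g, ["a"], ["b"])
    assert "z" in sub.nodes and "x" not in sub.nodes and "y" not in sub.nodes


def test_subnetwork_node_set_is_minimal():
    """Every included intermediate lies on some geodesic (removal breaks it)."""
    import random

    rng = random.Random(7)
    nodes = [f"n{i}" for i in range(12)]
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(
        (a, b) for a, b in itertools.combinations(nodes, 2) if rng.random() < 0.3
    )
    A, B = nodes[:2], nodes[2:4]
    sub = extract_subnetwork(g, A, B)
    for u in set(sub.nodes) - set(A) - set(B):
        on_some = False
        for a in A:
            for b in B:
                if not nx.has_path(g, a, b):
                    continue
                d = nx.shortest_path_length(g, a, b)
                da = nx.shortest_path_length(g, a, u) if nx.has_path(g, a, u) else None
                db = nx.shortest_path_length(g, u, b) if nx.has_path(g, u, b) else None
                if da is not None and db is not None and da + db == d:
                    on_some = True
        assert on_some, f"{u} is on no geodesic"


# --- candidate features -----------------------------------------------------


def test_candidate_features_distances_and_flags():
    records = [
        _rec(["bait", "s1"]),
        _rec(["bait", "s2"]),
        _rec(["c1", "bait"]),
        _rec(["c2", "s1"]),
        _rec(["c2", "s2"]),
        _rec(["c1", "c2", "q"], kind="complex"),
    ]
    g = build_network_from_records(records)
    feats = candidate_network_features(g, ["c1", "c2", "c3"], "bait", ["s1", "s2"])
    assert feats["c1"].parkin_nd == 1
    assert feats["c2"].seed_nd == 1 and feats["c2"].seed_nd_count == 2
    assert feats["c2"].seed_interactors == {"s1", "s2"}
    # c1 and c2 share a complex-expanded edge
    assert feats["c1"].not_complex is False and feats["c2"].not_complex is False
    assert feats["c3"].degree is None and feats["c3"].not_complex is None


def test_not_complex_true_for_binary_only_neighbor():
    g = build_network_from_records([_rec(["c1", "c2"]), _rec(["c1", "s1"])])
    feats = candidate_network_features(g, ["c1", "c2"], "bait", ["s1"])
    assert feats["c1"].not_complex is True


def test_adding_edge_never_increases_distance():
    rng_edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
    g = nx.Graph(rng_edges)
    before = shortest_distances(g, ["a"])
    g.add_edge("a", "d")
    after = shortest_distances(g, ["a"])
    for node, sd in before.items():
        assert after[node].distance <= sd.distance
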