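"""Enrichment statistics: exact tails, FDR, local adjustment, shared flags."""

import itertools
import math
import random

import numpy as np
import pytest

from tapprio.enrichment import (
    classic_enrichment,
    dual_significant_terms,
    enrich,
    gene_set_enrichment,
    hypergeom_upper_tail,
    local_adjusted_enrichment,
    read_gene_set_collection,
    shared_term_flags,
)
from tapprio.ontology import load_ontology, propagate

from conftest import write_obo


def enumeration_tail(k: int, n: int, K: int, N: int) -> float:
    """Exhaustive oracle: count draws of size n with >= k marked items."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


def test_tail_trivial_cases():
    assert hypergeom_upper_tail(0, 5, 3, 10) == 1.0
    assert hypergeom_upper_tail(4, 4, 4, 4) == 1.0
    assert hypergeom_upper_tail(4, 4, 5, 10) == pytest.approx(5 / 210)
    with pytest.raises(ValueError):
        hypergeom_upper_tail(5, 4, 3, 10)


def test_tail_matches_enumeration_all_configs_up_to_N8():
    """Spot layer of the exhaustive check (full N<=12 sweep in acceptance)."""
    for N in range(1, 9):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(n, K) + 1):
                    assert hypergeom_upper_tail(k, n, K, N) == pytest.approx(
                        enumeration_tail(k, n, K, N), abs=1e-12
                    )


def test_log_space_stability_for_tiny_tails():
    p = hypergeom_upper_tail(90, 100, 100, 10000)
    assert 0 < p < 1e-100  # would underflow to 0 in naive summation


@pytest.fixture
def two_branch_corpus(tmp_path):
    """Root with two branches; a leaf under branch one carries the signal."""
    p = tmp_path / "enrich.obo"
    write_obo(
        p,
        """
        [Term]
        id: R
        name: root

        [Term]
        id: P1
        name: parent one
        is_a: R

        [Term]
        id: P2
        name: parent two
        is_a: R

        [Term]
        id: L1
        name: leaf one
        is_a: P1

        [Term]
        id: L2
        name: leaf two
        is_a: P2
        """,
    )
    dag = load_ontology(p)
    direct = {}
    for i in range(10):
        direct[f"sig{i}"] = {"L1"}
    for i in range(10):
        direct[f"oth{i}"] = {"L2"}
    for i in range(20):
        direct[f"bg{i}"] = {"R"}
    return dag, propagate(dag, direct)


def test_classic_enrichment_top_term_and_fdr(two_branch_corpus):
    dag, ann = two_branch_corpus
    study = {f"sig{i}" for i in range(10)}
    results = {r.term: r for r in classic_enrichment(study, dag, ann)}
    assert results["L1"].classic_p == min(r.classic_p for r in results.values())
    assert results["L1"].study_count == 10
    for r in results.values():
        assert r.classic_fdr >= r.classic_p
        assert 0 <= r.classic_p <= 1


def test_empty_study_returns_empty(two_branch_corpus):
    dag, ann = two_branch_corpus
    assert classic_enrichment(set(), dag, ann) == []


def test_bh_adjustment_hand_computed(two_branch_corpus):
    from statsmodels.stats.multitest import multipletests

    _, fdr, _, _ = multipletests([0.01, 0.02, 0.04], method="fdr_bh")
    assert list(np.round(fdr, 10)) == [0.03, 0.03, 0.04]


def test_bh_monotone_and_bounded(two_branch_corpus):
    dag, ann = two_branch_corpus
    results = classic_enrichment({f"sig{i}" for i in range(5)}, dag, ann)
    by_p = sorted(results, key=lambda r: r.classic_p)
    fdrs = [r.classic_fdr for r in by_p]
    assert fdrs == sorted(fdrs)
    assert all(r.classic_fdr >= r.classic_p for r in results)


def test_elim_discounts_parent_fully_explained_by_child(two_branch_corpus):
    dag, ann = two_branch_corpus
    study = {f"sig{i}" for i in range(10)}
    classic = {r.term: r.classic_p for r in classic_enrichment(study, dag, ann)}
    local = local_adjusted_enrichment(study, dag, ann, significance_cutoff=0.01)
    # the leaf keeps its signal; its parent (same annotated set) is discounted
    assert local["L1"] == pytest.approx(classic["L1"])
    assert local["P1"] > classic["P1"] * 100


def test_elim_noop_on_independent_branches(two_branch_corpus):
    dag, ann = two_branch_corpus
    # weak study: nothing reaches the elim cutoff, so no removal happens
    study = {"sig0", "oth0", "bg0"}
    classic = {r.term: r.classic_p for r in classic_enrichment(study, dag, ann)}
    local = local_adjusted_enrichment(study, dag, ann, significance_cutoff=0.01)
    for term, p in classic.items():
        assert local[term] == pytest.approx(p)


def test_elim_with_cutoff_zero_equals_classic(two_branch_corpus):
    dag, ann = two_branch_corpus
    study = {f"sig{i}" for i in range(10)}
    classic = {r.term: r.classic_p for r in classic_enrichment(study, dag, ann)}
    local = local_adjusted_enrichment(study, dag, ann, significance_cutoff=0.0)
    for term, p in classic.items():
        assert local[term] == pytest.approx(p)


def test_type_one_error_calibration_under_uniform_null():
    """Raw classic p-values are calibrated: ~5% fall below 0.05 by chance."""
    rng = random.Random(11)
    import networkx as nx

    from tapprio.ontology import GoDag

    g = nx.DiGraph()
    g.add_node("R", name="root")
    terms = [f"T{i}" for i in range(30)]
    for t in terms:
        g.add_edge(t, "R")
    dag = GoDag(g)
    proteins = [f"p{i}" for i in range(100)]
    direct = {p: set() for p in proteins}
    for t in terms:
        for p in rng.sample(proteins, 30):
            direct[p].add(t)
    ann = propagate(dag, direct)
    below = total = 0
    for _ in range(500):
        study = rng.sample(proteins, 20)
        for r in classic_enrichment(study, dag, ann, universe=proteins):
            if r.term == "R":
                continue
            total += 1
            below += r.classic_p <= 0.05
    rate = below / total
    # discreteness keeps the attained level at or slightly below nominal
    assert 0.02 <= rate <= 0.07


def test_shared_term_flags_descendant_and_explicit_terms(two_branch_corpus):
    dag, ann = two_branch_corpus
    study_a = {f"sig{i}" for i in range(10)}
    study_b = {f"sig{i}" for i in range(6)}
    res_a = enrich(study_a, dag, ann)
    res_b = enrich(study_b, dag, ann)
    shared = dual_significant_terms(res_a, res_b, cutoff=1e-3)
    assert "L1" in shared
    flags = shared_term_flags(
        res_a, res_b, dag, ann, ["sig0", "oth0", "bg0"], cutoff=1e-3
    )
    assert flags["sig0"] is True and flags["oth0"] is False
    # explicit comparison terms: annotation to a descendant flags the protein
    flags2 = shared_term_flags(
        res_a, res_b, dag, ann, ["sig0", "oth0"], comparison_terms=["P1"]
    )
    assert flags2 == {"sig0": True, "oth0": False}


def test_gene_set_collection_round(tmp_path, two_branch_corpus):
    dag, ann = two_branch_corpus
    gmt = tmp_path / "c.gmt.tsv"
    gmt.write_text(
        "hit\tdesc\tsig0\tsig1\tsig2\tsig3\n"
        "miss\tdesc\tbg0\tbg1\n"
    )
    collection = read_gene_set_collection(gmt)
    res = gene_set_enrichment(
        {f"sig{i}" for i in range(4)}, collection, ann.proteins()
    )
    by_name = {r.term: r for r in res}
    assert by_name["hit"].study_count == 4
    assert by_name["hit"].classic_p < by_name["miss"].classic_p
    assert math.isclose(by_name["miss"].classic_p, 1.0)
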