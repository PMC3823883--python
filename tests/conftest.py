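"""Shared fixtures: tiny ontologies, annotation corpora, and file builders."""

from __future__ import annotations

import textwrap

import pytest

from tapprio.ontology import AnnotationSet, GoDag, load_ontology, propagate


def write_obo(path, stanzas: str) -> None:
    path.write_text("format-version: 1.2\nontology: test\n" + textwrap.dedent(stanzas))


@pytest.fixture
def chain_dag(tmp_path) -> GoDag:
    """root <- A <- B is_a chain."""
    p = tmp_path / "chain.obo"
    write_obo(
        p,
        """
        [Term]
        id: GO:0000001
        name: root
        namespace: biological_process

        [Term]
        id: GO:0000002
        name: A
        namespace: biological_process
        is_a: GO:0000001

        [Term]
        id: GO:0000003
        name: B
        namespace: biological_process
        is_a: GO:0000002
        """,
    )
    return load_ontology(p)


@pytest.fixture
def chain_corpus(chain_dag) -> AnnotationSet:
    """Four proteins on the chain giving p(A)=0.5 and p(B)=0.25."""
    direct = {
        "w": {"GO:0000001"},
        "x": {"GO:0000002"},
        "y": {"GO:0000003"},
        "z": {"GO:0000001"},
    }
    return propagate(chain_dag, direct)


@pytest.fixture
def branched_dag(tmp_path) -> GoDag:
    """Two disjoint branches under the root, two leaves each."""
    p = tmp_path / "branched.obo"
    write_obo(
        p,
        """
        [Term]
        id: R
        name: root
        namespace: biological_process

        [Term]
        id: P1
        name: branch one
        is_a: R

        [Term]
        id: P2
        name: branch two
        is_a: R

        [Term]
        id: L1a
        name: leaf 1a
        is_a: P1

        [Term]
        id: L1b
        name: leaf 1b
        is_a: P1

        [Term]
        id: L2a
        name: leaf 2a
        is_a: P2

        [Term]
        id: L2b
        name: leaf 2b
        is_a: P2
        """,
    )
    return load_ontology(p)


@pytest.fixture
def sets_file(tmp_path):
    def _write(rows, name="sets.tsv"):
        p = tmp_path / name
        p.write_text("".join("\t".join(r) + "\n" for r in rows))
        return p

    return _write
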