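"""Minimal GO-style ontology handling: DAG, propagation, slim flags.

Only ``is_a`` edges are traversed; annotations are propagated upward to all
ancestors (the "true path" rule), and slim membership asks whether a protein
is annotated to a slim term or any of its descendants — equivalent, under
propagation, to testing propagated annotations against the slim itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .registry import FormatError

log = logging.getLogger(__name__)


class GoDag:
    """An is_a DAG over ontology terms.

    Internally a :class:`networkx.DiGraph` with edges child -> parent, so
    "ancestors" of a term are its reachable generalizations.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            raise FormatError("ontology is_a graph contains a cycle")
        self._g = graph
        self._anc = lru_cache(maxsize=None)(self._ancestors_uncached)
        self._desc = lru_cache(maxsize=None)(self._descendants_uncached)

    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def terms(self) -> list[str]:
        return list(self._g.nodes)

    def name(self, term: str) -> str:
        return self._g.nodes[term].get("name", term)

    def namespace(self, term: str) -> str | None:
        return self._g.nodes[term].get("namespace")

    def parents(self, term: str) -> set[str]:
        self._check(term)
        return set(self._g.successors(term))

    def children(self, term: str) -> set[str]:
        self._check(term)
        return set(self._g.predecessors(term))

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        self._check(term)
        anc = set(self._anc(term))
        if include_self:
            anc.add(term)
        return anc

    def descendants(self, term: str, include_self: bool = True) -> set[str]:
        self._check(term)
        desc = set(self._desc(term))
        if include_self:
            desc.add(term)
        return desc

    def depth(self, term: str) -> int:
        """Longest is_a path from the term up to a root (root depth 0)."""
        self._check(term)
        return self._depth(term)

    @lru_cache(maxsize=None)
    def _depth(self, term: str) -> int:
        parents = set(self._g.successors(term))
        if not parents:
            return 0
        return 1 + max(self._depth(p) for p in parents)

    def _ancestors_uncached(self, term: str) -> frozenset[str]:
        return frozenset(nx.descendants(self._g, term))  # edges point upward

    def _descendants_uncached(self, term: str) -> frozenset[str]:
        return frozenset(nx.ancestors(self._g, term))

    def _check(self, term: str) -> None:
        if term not in self._g:
            raise KeyError(f"unknown ontology term: {term!r}")


def load_ontology(path: str | Path) -> GoDag:
    """Load an OBO 1.2 flat file, keeping is_a edges only.

    Obsolete stanzas are dropped; a cycle in the is_a graph is a fatal
    format error.
    """
    multi = obonet.read_obo(path, ignore_obsolete=True)
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        g.add_node(
            node,
            name=data.get("name", node),
            namespace=data.get("namespace"),
        )
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return GoDag(g)


@dataclass
class AnnotationSet:
    """Direct and ancestor-propagated protein -> term annotations."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]] = field(default_factory=dict)

    def proteins(self) -> set[str]:
        return set(self.direct)

    def annotated_to(self, term: str, propagated: bool = True) -> set[str]:
        table = self.propagated if propagated else self.direct
        return {p for p, ts in table.items() if term in ts}


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a GAF-like ``protein_id TAB term_id [TAB evidence]`` table."""
    direct: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 columns")
            direct.setdefault(fields[0], set()).add(fields[1])
    return direct


def propagate(dag: GoDag, direct: Mapping[str, Iterable[str]]) -> AnnotationSet:
    """Close direct annotations under is_a ancestors.

    Annotations to terms absent from the DAG are dropped with a warning.
    """
    clean: dict[str, set[str]] = {}
    prop: dict[str, set[str]] = {}
    for protein, terms in direct.items():
        kept = set()
        closure: set[str] = set()
        for t in terms:
            if t not in dag:
                log.warning("annotation of %s to unknown term %s dropped", protein, t)
                continue
            kept.add(t)
            closure |= dag.ancestors(t)
        clean[protein] = kept
        prop[protein] = closure
    return AnnotationSet(direct=clean, propagated=prop)


def slim_membership(
    annotations: AnnotationSet, slim: Iterable[str], dag: GoDag
) -> dict[str, bool]:
    """Flag proteins annotated to a slim term or any of its descendants."""
    slim_closure: set[str] = set()
    for t in slim:
        slim_closure |= dag.descendants(t)
    return {
        p: bool(terms & slim_closure)
        for p, terms in annotations.direct.items()
    }
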