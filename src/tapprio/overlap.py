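"""Overlap significance against external gene sets.

External evidence (genetic-modifier screens in another organism, published
interactor or ubiquitylation lists, a second bait's TAP screen) arrives as
plain gene sets, optionally in a foreign identifier space that is first
pushed through a many-to-many ortholog table. Significance of an overlap is
the one-sided hypergeometric tail — equivalently one-sided Fisher on the
2x2 table — against a caller-chosen universe, and results always carry the
universe label, since the same overlap can be tested against several
universes of very different size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .enrichment import hypergeom_upper_tail

log = logging.getLogger(__name__)


def map_orthologs(
    gene_set: Iterable[str], ortholog_table: Mapping[str, set[str]]
) -> tuple[set[str], set[str]]:
    """Map a gene set through a many-to-many ortholog table.

    Returns (union of all targets of all sources, unmapped sources).
    """
    mapped: set[str] = set()
    unmapped: set[str] = set()
    for g in gene_set:
        targets = ortholog_table.get(g)
        if targets:
            mapped |= targets
        else:
            unmapped.add(g)
    if unmapped:
        log.info("%d source genes had no ortholog mapping", len(unmapped))
    return mapped, unmapped


@dataclass
class OverlapTest:
    size_a: int
    size_b: int
    overlap: int
    universe_size: int
    p_value: float
    universe_label: str = ""


def overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str] | int,
    universe_label: str = "",
) -> OverlapTest:
    """Hypergeometric overlap test between two sets within a universe.

    ``universe`` may be an explicit member collection (set members outside
    it are dropped with a warning) or a bare size when only the count is
    known, in which case both sets are trusted to lie within it.
    """
    a, b = set(set_a), set(set_b)
    if isinstance(universe, int):
        n_universe = universe
        if n_universe <= 0:
            raise ValueError("universe size must be positive")
    else:
        u = set(universe)
        if not u:
            raise ValueError("empty universe")
        dropped = (len(a - u), len(b - u))
        if any(dropped):
            log.warning(
                "dropped %d/%d members of A/B outside universe %r",
                *dropped, universe_label,
            )
        a &= u
        b &= u
        n_universe = len(u)
    k = len(a & b)
    p = hypergeom_upper_tail(k, len(a), len(b), n_universe)
    return OverlapTest(len(a), len(b), k, n_universe, p, universe_label)


def flag_candidates(
    candidates: Iterable[str], flag_sets: Mapping[str, set[str]]
) -> dict[str, dict[str, bool]]:
    """Per-candidate membership booleans for each labelled evidence set.

    Used for the external-screen columns of the feature table; the tag-
    artifact flag (interaction with the purification tag's binding protein)
    is derived upstream as the interactome neighborhood of that protein and
    passed in as one more labelled set.
    """
    return {c: {lab: c in s for lab, s in flag_sets.items()} for c in candidates}


def write_overlap_tests(tests: Sequence[OverlapTest], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# size_a\tsize_b\toverlap\tuniverse_size\tp_value\tuniverse\n")
        for t in tests:
            fh.write(
                f"{t.size_a}\t{t.size_b}\t{t.overlap}\t{t.universe_size}"
                f"\t{t.p_value:.6g}\t{t.universe_label}\n"
            )
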