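"""Gene-set / GO over-representation analysis.

Two scores per ontology term:

* classic — one-sided hypergeometric (equivalently one-sided Fisher) upper
  tail on the 2x2 study/population table, Benjamini–Hochberg adjusted
  across all tested terms;
* local — an elim-style locally adjusted p-value: terms are tested from the
  most specific upward, and whenever a term is significant at the local
  cutoff its annotated proteins are removed from all of its ancestors
  before those are tested. Generic terms whose signal is fully explained by
  a specific descendant are thereby down-weighted.

A flat (DAG-free) variant over GMT-like collections serves pathway
over-representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .ontology import AnnotationSet, GoDag
from .registry import FormatError

log = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K marked, n drawn).

    scipy's survival function is computed in log space, so tiny tails keep
    full relative precision.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    term: str
    study_count: int
    study_size: int
    population_count: int
    population_size: int
    classic_p: float
    classic_fdr: float | None = None
    local_p: float | None = None
    name: str = ""


def _term_index(
    annotations: AnnotationSet, universe: set[str]
) -> dict[str, set[str]]:
    """term -> set of universe proteins annotated (propagated) to it."""
    index: dict[str, set[str]] = {}
    for protein in universe:
        for t in annotations.propagated.get(protein, ()):
            index.setdefault(t, set()).add(protein)
    return index


def classic_enrichment(
    study: Iterable[str],
    dag: GoDag,
    annotations: AnnotationSet,
    universe: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation per term, BH-adjusted.

    The universe defaults to every annotated protein in the corpus. Every
    term with at least one annotated universe protein is tested.
    """
    universe_set = (
        set(universe) if universe is not None else set(annotations.propagated)
    )
    study_set = set(study) & universe_set
    if not study_set:
        log.warning("empty study set; no enrichment computed")
        return []
    index = _term_index(annotations, universe_set)
    N, n = len(universe_set), len(study_set)
    results = []
    for term, pop in sorted(index.items()):
        k = len(study_set & pop)
        results.append(
            EnrichmentResult(
                term=term,
                study_count=k,
                study_size=n,
                population_count=len(pop),
                population_size=N,
                classic_p=hypergeom_upper_tail(k, n, len(pop), N),
                name=dag.name(term) if term in dag else term,
            )
        )
    _, fdr, _, _ = multipletests([r.classic_p for r in results], method="fdr_bh")
    for r, q in zip(results, fdr):
        r.classic_fdr = float(q)
    return results


def local_adjusted_enrichment(
    study: Iterable[str],
    dag: GoDag,
    annotations: AnnotationSet,
    universe: Iterable[str] | None = None,
    significance_cutoff: float = 0.01,
) -> dict[str, float]:
    """Elim-style locally adjusted p-value per term.

    Terms are processed in decreasing DAG depth. When a term's p-value at
    test time is <= ``significance_cutoff``, its annotated proteins are
    removed from every ancestor's study/population counts before the
    ancestor is tested. With cutoff 0 nothing is ever removed and the
    result equals the classic raw p-values.
    """
    universe_set = (
        set(universe) if universe is not None else set(annotations.propagated)
    )
    study_set = set(study) & universe_set
    if not study_set:
        return {}
    index = _term_index(annotations, universe_set)
    N, n = len(universe_set), len(study_set)
    removed: dict[str, set[str]] = {t: set() for t in index}
    local_p: dict[str, float] = {}
    order = sorted(
        index, key=lambda t: (-(dag.depth(t) if t in dag else 0), t)
    )
    for term in order:
        pop = index[term] - removed[term]
        k = len(study_set & pop)
        p = hypergeom_upper_tail(k, n, len(pop), N)
        local_p[term] = p
        if p <= significance_cutoff and term in dag:
            culprits = index[term]
            for anc in dag.ancestors(term, include_self=False):
                if anc in removed:
                    removed[anc] |= culprits
    return local_p


def enrich(
    study: Iterable[str],
    dag: GoDag,
    annotations: AnnotationSet,
    universe: Iterable[str] | None = None,
    local_cutoff: float = 0.01,
) -> list[EnrichmentResult]:
    """Classic + local scores in one result list."""
    results = classic_enrichment(study, dag, annotations, universe)
    local = local_adjusted_enrichment(
        study, dag, annotations, universe, significance_cutoff=local_cutoff
    )
    for r in results:
        r.local_p = local.get(r.term)
    return results


def dual_significant_terms(
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
    cutoff: float = 1e-3,
) -> set[str]:
    """Terms with classic p <= cutoff in both result lists."""
    sig_a = {r.term for r in results_a if r.classic_p <= cutoff}
    sig_b = {r.term for r in results_b if r.classic_p <= cutoff}
    return sig_a & sig_b


def shared_term_flags(
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
    dag: GoDag,
    annotations: AnnotationSet,
    candidates: Iterable[str],
    cutoff: float = 1e-3,
    comparison_terms: Iterable[str] | None = None,
) -> dict[str, bool]:
    """Shared-process flag (GOComp analogue) per candidate.

    A candidate is flagged iff it is annotated to any designated comparison
    term or a descendant thereof. The comparison terms default to the
    processes significant (classic p <= cutoff) in both datasets; an
    explicit curated list can be supplied instead, mirroring the published
    selection of five dual-significant processes plus protein folding.
    """
    if comparison_terms is None:
        comparison_terms = dual_significant_terms(results_a, results_b, cutoff)
    closure: set[str] = set()
    for t in comparison_terms:
        if t in dag:
            closure |= dag.descendants(t)
    return {
        c: bool(annotations.direct.get(c, set()) & closure) for c in candidates
    }


def read_gene_set_collection(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT-like ``set_name TAB description TAB member...`` file."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            sets[fields[0]] = set(f for f in fields[2:] if f)
    return sets


def gene_set_enrichment(
    study: Iterable[str],
    collection: Mapping[str, set[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Flat over-representation over a pathway collection (no DAG).

    Pathway members outside the universe are ignored; BH adjustment across
    all sets in the collection.
    """
    universe_set = set(universe)
    study_set = set(study) & universe_set
    N, n = len(universe_set), len(study_set)
    results = []
    for name, members in sorted(collection.items()):
        pop = members & universe_set
        if not pop:
            continue
        k = len(study_set & pop)
        results.append(
            EnrichmentResult(
                term=name,
                study_count=k,
                study_size=n,
                population_count=len(pop),
                population_size=N,
                classic_p=hypergeom_upper_tail(k, n, len(pop), N),
                name=name,
            )
        )
    if results:
        _, fdr, _, _ = multipletests([r.classic_p for r in results], method="fdr_bh")
        for r, q in zip(results, fdr):
            r.classic_fdr = float(q)
    return results


def write_enrichment_table(
    results: Sequence[EnrichmentResult], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "# term\tname\tstudy_count\tstudy_size\tpopulation_count"
            "\tpopulation_size\tclassic_p\tclassic_fdr\tlocal_p\n"
        )
        for r in sorted(results, key=lambda r: (r.classic_p, r.term)):
            local = "" if r.local_p is None else f"{r.local_p:.6g}"
            fdr = "" if r.classic_fdr is None else f"{r.classic_fdr:.6g}"
            fh.write(
                f"{r.term}\t{r.name}\t{r.study_count}\t{r.study_size}"
                f"\t{r.population_count}\t{r.population_size}"
                f"\t{r.classic_p:.6g}\t{fdr}\t{local}\n"
            )
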