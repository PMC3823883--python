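"""GO semantic functional similarity, similarity networks, and clustering.

Protein-level similarity is the best-match average (BMA) of pairwise term
similarities between the two proteins' direct annotation sets, with either
the Lin kernel, 2·IC(MICA)/(IC(t1)+IC(t2)), or the relevance kernel
(simRel), which additionally discounts by (1 − p(MICA)) so that matches on
near-root terms count less. IC(t) = −ln p(t) with p(t) the fraction of the
annotated corpus annotated to t or a descendant.

Proteins whose similarity reaches a threshold (0.7 by default, inclusive)
are connected in a similarity network, and densely connected, possibly
overlapping modules are found by greedy cohesiveness maximization with
empirical significance from edge-weight permutations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .ontology import AnnotationSet, GoDag

log = logging.getLogger(__name__)


def information_content(
    annotations: AnnotationSet, dag: GoDag
) -> dict[str, float]:
    """Corpus information content per term.

    Terms annotating nothing in the corpus have undefined IC and are
    excluded. The root (p = 1) gets IC exactly 0.
    """
    n_annotated = sum(1 for ts in annotations.propagated.values() if ts)
    if n_annotated == 0:
        return {}
    counts: dict[str, int] = {}
    for terms in annotations.propagated.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return {
        t: -math.log(c / n_annotated) for t, c in counts.items() if t in dag
    }


def _mica(t1: str, t2: str, dag: GoDag, ic: Mapping[str, float]) -> str | None:
    common = dag.ancestors(t1) & dag.ancestors(t2)
    scored = [t for t in common if t in ic]
    if not scored:
        return None
    return max(scored, key=lambda t: (ic[t], t))


def term_similarity(
    t1: str,
    t2: str,
    dag: GoDag,
    ic: Mapping[str, float],
    kernel: str = "lin",
) -> float:
    """Semantic similarity between two terms in [0, 1].

    lin(t,t) = 1 for any non-root term; two terms whose only common
    ancestor is the root score 0 (the root's IC is 0).
    """
    if t1 not in ic or t2 not in ic:
        raise KeyError(f"term without information content: {t1!r} / {t2!r}")
    mica = _mica(t1, t2, dag, ic)
    if mica is None:
        return 0.0
    denom = ic[t1] + ic[t2]
    if denom <= 0.0:
        return 0.0  # both terms are root-probability terms
    lin = 2.0 * ic[mica] / denom
    if kernel == "lin":
        return min(lin, 1.0)
    if kernel == "simrel":
        p_mica = math.exp(-ic[mica])
        return min(lin * (1.0 - p_mica), 1.0)
    raise ValueError(f"unknown kernel: {kernel!r}")


def _bma(
    terms1: Sequence[str],
    terms2: Sequence[str],
    dag: GoDag,
    ic: Mapping[str, float],
    kernel: str,
) -> float:
    sim = np.array(
        [[term_similarity(a, b, dag, ic, kernel) for b in terms2] for a in terms1]
    )
    return float((sim.max(axis=1).mean() + sim.max(axis=0).mean()) / 2.0)


def protein_funsim(
    p1: str,
    p2: str,
    annotations: AnnotationSet,
    dag: GoDag,
    ic: Mapping[str, float],
    kernel: str = "lin",
    variants: Mapping[str, Sequence[str]] | None = None,
) -> float | None:
    """Best-match-average similarity between two proteins.

    Returns ``None`` when either protein carries no IC-scored direct
    annotation (such proteins are excluded from similarity networks).
    With ``variants`` (protein -> alternative accession list, each with its
    own annotation set), the score is the maximum over variant pairs,
    matching the many-to-many accession mapping convention.
    """
    ids1 = list(variants.get(p1, [p1])) if variants else [p1]
    ids2 = list(variants.get(p2, [p2])) if variants else [p2]
    best: float | None = None
    for a in ids1:
        terms_a = sorted(t for t in annotations.direct.get(a, ()) if t in ic)
        if not terms_a:
            continue
        for b in ids2:
            terms_b = sorted(t for t in annotations.direct.get(b, ()) if t in ic)
            if not terms_b:
                continue
            score = _bma(terms_a, terms_b, dag, ic, kernel)
            if best is None or score > best:
                best = score
    return best


def pairwise_similarity(
    proteins: Iterable[str],
    annotations: AnnotationSet,
    dag: GoDag,
    ic: Mapping[str, float],
    kernel: str = "lin",
    variants: Mapping[str, Sequence[str]] | None = None,
) -> dict[frozenset[str], float]:
    """All-pairs protein similarity; unannotated proteins are skipped."""
    proteins = sorted(set(proteins))
    scores: dict[frozenset[str], float] = {}
    for p1, p2 in combinations(proteins, 2):
        s = protein_funsim(p1, p2, annotations, dag, ic, kernel, variants)
        if s is not None:
            scores[frozenset((p1, p2))] = s
    return scores


def build_funsim_network(
    proteins: Iterable[str],
    scores: Mapping[frozenset[str], float],
    threshold: float = 0.7,
) -> nx.Graph:
    """Similarity network: edge iff score >= threshold (inclusive).

    All supplied proteins appear as nodes, so proteins without any
    similar partner are retained as isolates.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(set(proteins)))
    for pair, score in scores.items():
        if score >= threshold:
            a, b = sorted(pair)
            g.add_edge(a, b, weight=float(score))
    return g


@dataclass
class Cluster:
    members: frozenset[str]
    cohesiveness: float
    p_value: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]


def _cohesiveness(g: nx.Graph, members: set[str], penalty: float) -> float:
    w_in = 0.0
    w_bound = 0.0
    for u in members:
        for v, data in g[u].items():
            w = data.get("weight", 1.0)
            if v in members:
                w_in += w / 2.0
            else:
                w_bound += w
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


def _grow_cluster(g: nx.Graph, seed: str, penalty: float) -> set[str]:
    members = {seed}
    score = _cohesiveness(g, members, penalty)
    while True:
        best_step: tuple[float, str, str] | None = None
        frontier = {v for u in members for v in g[u] if v not in members}
        for v in sorted(frontier):
            s = _cohesiveness(g, members | {v}, penalty)
            if s > score and (best_step is None or s > best_step[0]):
                best_step = (s, "add", v)
        if len(members) > 1:
            for v in sorted(members):
                s = _cohesiveness(g, members - {v}, penalty)
                if s > score and (best_step is None or s > best_step[0]):
                    best_step = (s, "remove", v)
        if best_step is None:
            return members
        score, op, node = best_step
        if op == "add":
            members.add(node)
        else:
            members.remove(node)


def _overlap_score(a: frozenset[str], b: frozenset[str]) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def find_clusters(
    graph: nx.Graph,
    min_size: int = 3,
    n_permutations: int = 1000,
    seed: int = 17,
    penalty: float = 2.0,
    merge_overlap: float = 0.8,
) -> ClusterResult:
    """Greedy cohesiveness clustering with empirical significance.

    Clusters are grown from the highest-strength unclaimed node, locally
    maximizing f(C) = w_in / (w_in + w_bound + penalty·|C|); overlapping
    clusters (match coefficient >= ``merge_overlap``) are merged. Each
    cluster's p-value is the fraction of edge-weight permutations (topology
    fixed, weights shuffled among edges) in which the same node set scores
    at least its observed cohesiveness. Deterministic for a given seed.
    """
    if graph.number_of_nodes() < min_size:
        return ClusterResult([])
    strength = {
        n: sum(d.get("weight", 1.0) for d in graph[n].values()) for n in graph
    }
    claimed: set[str] = set()
    raw: list[set[str]] = []
    for node in sorted(graph.nodes, key=lambda n: (-strength[n], n)):
        if node in claimed or strength[node] == 0:
            continue
        members = _grow_cluster(graph, node, penalty)
        claimed |= members
        if len(members) >= min_size:
            raw.append(members)

    merged = [frozenset(c) for c in raw]
    changed = True
    while changed:
        changed = False
        for i, j in combinations(range(len(merged)), 2):
            if _overlap_score(merged[i], merged[j]) >= merge_overlap:
                union = merged[i] | merged[j]
                merged = [c for k, c in enumerate(merged) if k not in (i, j)]
                merged.append(union)
                changed = True
                break

    rng = np.random.default_rng(seed)
    edges = sorted(graph.edges)
    weights = np.array([graph[u][v].get("weight", 1.0) for u, v in edges])
    clusters = []
    for members in sorted(merged, key=lambda c: sorted(c)):
        observed = _cohesiveness(graph, set(members), penalty)
        # Only which weights land inside vs on the boundary of C matters, so
        # cohesiveness under a weight permutation reduces to two masked sums.
        inside = np.array([(u in members) + (v in members) for u, v in edges])
        base = penalty * len(members)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(weights)
            w_in = perm[inside == 2].sum()
            w_bound = perm[inside == 1].sum()
            denom = w_in + w_bound + base
            f = w_in / denom if denom > 0 else 0.0
            if f >= observed - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
        clusters.append(Cluster(members, observed, p))
    clusters.sort(key=lambda c: (c.p_value, -c.cohesiveness, sorted(c.members)))
    return ClusterResult(clusters)


def write_similarity_matrix(
    scores: Mapping[frozenset[str], float], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\tscore\n")
        for pair in sorted(scores, key=sorted):
            a, b = sorted(pair)
            fh.write(f"{a}\t{b}\t{scores[pair]:.6f}\n")


def write_clusters(result: ClusterResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# cluster_id\tmember\tcohesiveness\tp_value\n")
        for i, c in enumerate(result.clusters, start=1):
            for m in sorted(c.members):
                fh.write(f"{i}\t{m}\t{c.cohesiveness:.6f}\t{c.p_value:.6g}\n")
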