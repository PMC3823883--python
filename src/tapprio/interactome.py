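"""Interactome construction and network-derived candidate features.

The interaction corpus mixes binary records (two interactors) and complex
records (>= 3 interactors with unspecified internal contacts). Complexes are
matrix-expanded: a k-member complex contributes all k(k-1)/2 pairwise edges,
each tagged with complex provenance. The deduplicated undirected graph over
all pairs is the full interactome (HNet analogue); the shortest-path
subnetwork (SpNet analogue) is induced by every geodesic between the screen
candidates and the disease-seed proteins, plus caller-supplied interactor
sets. Candidate features (distance to bait, minimum distance to any seed and
the number of seeds attaining it, degree, complex sharing) feed the
prioritization decision tree.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .registry import FormatError, ProteinRef

log = logging.getLogger(__name__)

#: Detection-method phrases marking computationally predicted interactions;
#: any record whose method contains one of these (case-insensitive) is dropped.
PREDICTED_METHOD_PHRASES = (
    "predicted",
    "interologs mapping",
    "confirmational text mining",
)


@dataclass
class InteractionRecord:
    members: list[ProteinRef]
    kind: str  # "binary" | "complex"
    detection_method: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("interaction record needs >= 2 members")
        # 2-member "complex" records carry no expansion ambiguity: demote.
        if self.kind == "complex" and len(self.members) == 2:
            log.warning(
                "2-member complex record %s reclassified as binary",
                [m.id for m in self.members],
            )
            self.kind = "binary"
        if self.kind == "binary" and len(self.members) != 2:
            raise ValueError("binary record must have exactly 2 members")
        if self.kind not in ("binary", "complex"):
            raise ValueError(f"unknown record kind: {self.kind!r}")


@dataclass(frozen=True)
class EdgeEvidence:
    has_binary_evidence: bool = False
    has_complex_evidence: bool = False

    def merge(self, other: "EdgeEvidence") -> "EdgeEvidence":
        return EdgeEvidence(
            self.has_binary_evidence or other.has_binary_evidence,
            self.has_complex_evidence or other.has_complex_evidence,
        )


def read_interactions(path: str | Path) -> list[InteractionRecord]:
    """Parse a MITAB-like TSV.

    Columns: record_id, ';'-joined member ids, kind, detection_method, source.
    Records with fewer than two members are skipped with a warning; other
    malformed lines raise :class:`FormatError` with the line number.
    """
    records: list[InteractionRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            member_ids = [m for m in fields[1].split(";") if m]
            if len(member_ids) < 2:
                log.warning("%s:%d: <2 members, record skipped", path, lineno)
                continue
            kind = fields[2]
            if kind not in ("binary", "complex"):
                raise FormatError(f"{path}:{lineno}: bad kind {kind!r}")
            if kind == "binary" and len(member_ids) != 2:
                # A binary tag on an n-ary member list is a format defect,
                # not an invariant to silently repair.
                raise FormatError(
                    f"{path}:{lineno}: binary record with {len(member_ids)} members"
                )
            records.append(
                InteractionRecord(
                    members=[ProteinRef(m) for m in member_ids],
                    kind=kind,
                    detection_method=fields[3] if len(fields) > 3 else "",
                    source=fields[4] if len(fields) > 4 else "",
                )
            )
    return records


def filter_predicted(
    records: Iterable[InteractionRecord],
    phrases: Sequence[str] = PREDICTED_METHOD_PHRASES,
) -> list[InteractionRecord]:
    """Drop records whose detection method marks a predicted interaction.

    Matching is case-insensitive substring; order is preserved.
    """
    lowered = tuple(p.lower() for p in phrases)
    kept = []
    for rec in records:
        method = rec.detection_method.lower()
        if any(p in method for p in lowered):
            continue
        kept.append(rec)
    return kept


def expand_complexes(
    records: Iterable[InteractionRecord],
) -> dict[frozenset[str], EdgeEvidence]:
    """Matrix-expand records into unordered pairs with merged provenance.

    A k-member complex yields exactly k(k-1)/2 pairs (after removing
    duplicate member ids); binary records yield one pair. Self-pairs are
    discarded.
    """
    pairs: dict[frozenset[str], EdgeEvidence] = {}

    def _add(a: str, b: str, ev: EdgeEvidence) -> None:
        if a == b:
            return
        key = frozenset((a, b))
        pairs[key] = pairs.get(key, EdgeEvidence()).merge(ev)

    for rec in records:
        ids = sorted({m.id for m in rec.members})
        if rec.kind == "binary":
            if len(ids) == 2:
                _add(ids[0], ids[1], EdgeEvidence(has_binary_evidence=True))
        else:
            for a, b in combinations(ids, 2):
                _add(a, b, EdgeEvidence(has_complex_evidence=True))
    return pairs


def build_network(pairs: Mapping[frozenset[str], EdgeEvidence]) -> nx.Graph:
    """Assemble the simple undirected interactome graph.

    Edge attributes ``has_binary`` / ``has_complex`` record provenance,
    OR-merged across duplicate pairs.
    """
    g = nx.Graph()
    for key, ev in pairs.items():
        a, b = sorted(key)
        if g.has_edge(a, b):
            g[a][b]["has_binary"] |= ev.has_binary_evidence
            g[a][b]["has_complex"] |= ev.has_complex_evidence
        else:
            g.add_edge(
                a, b,
                has_binary=ev.has_binary_evidence,
                has_complex=ev.has_complex_evidence,
            )
    return g


def build_network_from_records(
    records: Iterable[InteractionRecord], drop_predicted: bool = True
) -> nx.Graph:
    """Convenience: filter, expand and assemble in one call."""
    if drop_predicted:
        records = filter_predicted(records)
    return build_network(expand_complexes(records))


def network_density(n_nodes: int, n_edges: int) -> float:
    """Undirected simple-graph density 2E / (V(V-1)); 0 (warned) for V < 2."""
    if n_nodes < 2:
        log.warning("density undefined for %d nodes; reporting 0", n_nodes)
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def network_stats(net: nx.Graph) -> dict:
    """Degrees, density and connected components of the graph."""
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "degrees": dict(net.degree()),
        "density": network_density(net.number_of_nodes(), net.number_of_edges()),
        "components": [set(c) for c in nx.connected_components(net)],
    }


@dataclass
class SourceDistance:
    """BFS result for one node against a source set."""

    distance: int
    n_sources_at_min: int
    sources_at_min: set[str]
    sources_at_distance_1: set[str]


def shortest_distances(
    net: nx.Graph, sources: Iterable[str]
) -> dict[str, SourceDistance]:
    """Unweighted shortest distance from every node to the nearest source.

    Returns, per reachable node: the minimum distance over sources present
    in the graph, the set (and count) of source proteins attaining that
    minimum, and the sources adjacent to the node. Nodes unreachable from
    every source are absent from the result (undefined), as are all nodes
    when no source is in the graph.
    """
    present = [s for s in sources if s in net]
    per_source: dict[str, dict[str, int]] = {}
    for s in present:
        per_source[s] = _bfs_lengths(net, s)
    result: dict[str, SourceDistance] = {}
    for node in net.nodes:
        dists = {s: d[node] for s, d in per_source.items() if node in d}
        if not dists:
            continue
        dmin = min(dists.values())
        at_min = {s for s, d in dists.items() if d == dmin}
        at_one = {s for s, d in dists.items() if d == 1}
        result[node] = SourceDistance(dmin, len(at_min), at_min, at_one)
    return result


def _bfs_lengths(net: nx.Graph, source: str) -> dict[str, int]:
    seen = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in net[u]:
            if v not in seen:
                seen[v] = seen[u] + 1
                queue.append(v)
    return seen


def extract_subnetwork(
    net: nx.Graph,
    set_a: Iterable[str],
    set_b: Iterable[str],
    extra_nodes: Iterable[str] = (),
) -> nx.Graph:
    """Shortest-path subnetwork between two protein sets.

    Nodes: A ∪ B ∪ every node lying on at least one geodesic between some
    a in A and b in B, plus ``extra_nodes`` (the caller's known-interactor
    sets). Edges: those of the parent graph induced on that node set. Only
    A↔B geodesics are considered, not paths within A or within B.

    A node u is on a geodesic a—b iff d(a,u) + d(u,b) == d(a,b); with
    per-source BFS maps from both sides this is checked in O(|V|·|A∪B|).
    """
    a_set = [a for a in set_a if a in net]
    b_set = [b for b in set_b if b in net]
    dist_a = {a: _bfs_lengths(net, a) for a in a_set}
    dist_b = {b: _bfs_lengths(net, b) for b in b_set}
    keep: set[str] = set(a_set) | set(b_set)
    keep.update(n for n in extra_nodes if n in net)
    for a in a_set:
        da = dist_a[a]
        for b in b_set:
            db = dist_b[b]
            if b not in da:
                continue  # disconnected pair
            d_ab = da[b]
            for u in net.nodes:
                if u in da and u in db and da[u] + db[u] == d_ab:
                    keep.add(u)
    return net.subgraph(keep).copy()


@dataclass
class NetworkFeatures:
    """Per-candidate network feature block (one slice of a feature row).

    ``None`` fields mean the protein is absent from the network (rendered
    as "–" on export).
    """

    parkin_nd: int | None = None
    seed_nd: int | None = None
    seed_nd_count: int | None = None
    seed_interactors: set[str] = field(default_factory=set)
    degree: int | None = None
    not_complex: bool | None = None


def candidate_network_features(
    distance_net: nx.Graph,
    candidates: Iterable[str],
    bait: str,
    seeds: Iterable[str],
    degree_net: nx.Graph | None = None,
) -> dict[str, NetworkFeatures]:
    """Compute the network feature block for each candidate.

    Distances (to bait and to the seed set) are measured in
    ``distance_net`` (typically the shortest-path subnetwork); degree is
    measured in ``degree_net`` (typically the full interactome) so that it
    reflects the whole interaction corpus. ``not_complex`` is true iff the
    candidate shares no complex-evidence edge with any *other* candidate.
    """
    if degree_net is None:
        degree_net = distance_net
    candidates = list(candidates)
    cand_set = set(candidates)
    seed_dist = shortest_distances(distance_net, seeds)
    bait_dist = shortest_distances(distance_net, [bait])

    out: dict[str, NetworkFeatures] = {}
    for c in candidates:
        if c not in distance_net:
            out[c] = NetworkFeatures()
            continue
        feats = NetworkFeatures()
        if c in bait_dist:
            feats.parkin_nd = bait_dist[c].distance
        sd = seed_dist.get(c)
        if sd is not None:
            feats.seed_nd = sd.distance
            feats.seed_nd_count = sd.n_sources_at_min
            feats.seed_interactors = sd.sources_at_distance_1
        feats.degree = degree_net.degree(c) if c in degree_net else None
        shares_complex = any(
            degree_net[c][nbr].get("has_complex", False)
            for nbr in (degree_net[c] if c in degree_net else ())
            if nbr in cand_set and nbr != c
        )
        feats.not_complex = not shares_complex
        out[c] = feats
    return out


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# node_a\tnode_b\thas_binary\thas_complex\n")
        for a, b, data in sorted(net.edges(data=True)):
            fh.write(
                f"{a}\t{b}\t{int(data.get('has_binary', False))}"
                f"\t{int(data.get('has_complex', False))}\n"
            )
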