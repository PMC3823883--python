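# Methods

This note documents the models and procedures implemented in `tapprio`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not show.

## Interactome model

Interaction records are either *binary* (exactly two interactors) or
*complex* (three or more interactors with unspecified internal contacts).
Complexes are matrix-expanded: a k-member complex contributes all
k(k−1)/2 unordered pairs, each tagged `has_complex` provenance; binary
records contribute one `has_binary` pair. Provenance flags are OR-merged
across duplicate pairs. The graph is simple and undirected: self-pairs
(duplicate member identifiers) are discarded, and a two-member record
labelled "complex" is demoted to binary — it carries no expansion
ambiguity, and treating it as complex evidence would inflate the
complex-sharing feature.

Records are filtered before expansion: any record whose detection method
contains (case-insensitive substring) one of *predicted*, *interologs
mapping* or *confirmational text mining* is dropped. Case-insensitivity is
our choice; database exports are inconsistent about capitalization and a
case-sensitive match would silently keep predicted records.

Distances are unweighted breadth-first distances. For a candidate set A
and seed set B, the shortest-path subnetwork contains A ∪ B plus every
node u with d(a,u) + d(u,b) = d(a,b) for some a∈A, b∈B — all geodesics,
not one arbitrary geodesic per pair — with edges induced from the parent
graph. Only A↔B geodesics are used, not within-A or within-B paths; the
candidate–candidate alternative would add nodes but cannot change any
candidate↔seed distance, since subgraph distances between preserved
geodesic endpoints are already exact. Candidate degree is reported from
the *full* network, not the subnetwork, so it reflects the whole
interaction corpus. The minimum-distance seed count (#ND) counts distinct
seed proteins at the minimum distance, not distinct shortest paths.

Density is the undirected simple-graph ratio 2E / (V(V−1)), reported as a
fraction; graphs with fewer than two nodes get density 0 with a warning.

## Ontology and annotation

Only `is_a` edges are traversed; obsolete terms are dropped at parse time
and a cycle is a fatal format error. Annotations are propagated to all
ancestors (true-path rule). Slim membership — "annotated to a slim term or
any descendant" — is implemented by closing the slim downward through
descendants and intersecting with direct annotations, which is equivalent
to testing propagated annotations against the slim itself. All evidence
codes are accepted; the pipeline has no evidence-quality model.

## Enrichment scores

The *classic* score is the one-sided hypergeometric upper tail
P(X ≥ k | N, K, n), identical to one-sided Fisher on the 2×2 table;
it is computed through the survival function in log space so that tails
far below double precision (p ≈ 10⁻¹⁵ and smaller) retain relative
accuracy. Benjamini–Hochberg FDR is applied across all tested terms. The
universe defaults to every annotated protein in the corpus; this is a
convention, and an explicit universe can be supplied.

The *local* score is an elim-style adjustment: terms are tested from the
deepest upward (depth = longest is_a path to a root), and whenever a
term's p-value at test time falls at or below the local cutoff (default
0.01), its annotated proteins are removed from every ancestor before the
ancestor is tested. Generic terms whose signal is fully explained by a
specific descendant are thereby down-weighted. With cutoff 0 the local
score equals the classic raw p-value. This is a published
topology-respecting adjustment implemented from first principles; the test
suite pins its qualitative contract (descendant keeps significance,
fully-explained ancestor collapses, independent branches unaffected, and
type-I calibration of the classic score under a uniform null).

The shared-process flag marks candidates annotated to any *comparison
term* or descendant. Comparison terms default to the processes significant
(classic p ≤ 10⁻³) in both the candidate set and the disease-related set;
a curated explicit list can be supplied instead, which is how the
published six-process comparison (five dual-significant processes plus
protein folding) is represented.

Pathway over-representation over flat GMT-like collections uses the same
hypergeometric machinery without any DAG adjustment.

## Functional similarity

IC(t) = −ln p(t), where p(t) is the fraction of annotated corpus proteins
annotated to t or a descendant; the root has IC 0, and terms annotating
nothing are excluded. Term similarity uses the Lin kernel
2·IC(MICA)/(IC(t₁)+IC(t₂)) by default, with the relevance kernel
(`simrel`, Lin × (1 − p(MICA))) available by flag; which variant produced
the historical published matrix is not recoverable, so both are provided
and the ≥ 0.7 edge-threshold semantics (inclusive) are preserved. Protein
similarity is the best-match average over *direct* term sets: the mean of
row maxima and column maxima of the pairwise term-similarity matrix. When
a protein maps to several accession variants, the protein score is the
maximum over variant pairs. Unannotated proteins have undefined similarity
and are excluded from similarity networks (retained as isolated nodes when
explicitly listed).

Clustering is greedy cohesiveness maximization over the weighted
similarity graph: clusters grow from the highest-strength unclaimed node,
adding or removing single nodes while
f(C) = w_in / (w_in + w_bound + penalty·|C|) improves; the node-count
penalty defaults to 2 and the overlap-merge threshold (match coefficient
|A∩B|²/(|A||B|)) to 0.8, the stated defaults of the published
overlapping-cluster method this emulates. Cluster significance is
empirical: edge weights are permuted over the fixed topology (default
1,000 permutations, seed 17) and the p-value is the add-one-smoothed
fraction of permutations reaching the observed cohesiveness; clusters with
p ≤ 0.05 are called significant. Results are deterministic given the seed.

## Overlap statistics

External gene sets are mapped through a many-to-many ortholog table (a
source mapping to k targets contributes all k; unmapped sources are
logged and, for screen-membership sets, retained verbatim so set sizes are
not silently shrunk). Overlap significance is the hypergeometric upper
tail against a caller-chosen universe — universes are configuration, not
constants, because the same overlap is legitimately tested against
universes of very different size (e.g. all human genes vs all genes of the
screen organism), and every result carries its universe label.

## Decision tree and ranking

With `interact` := (minimum seed distance = 1), the first-match rules are:

| level | rule |
|---|---|
| 0 | reported bait interactor (bait distance ≤ 1), or the bait itself |
| 1 | interact with ≥ 2 distinct seeds |
| 2 | interact and functionally similar (≥ 0.7) to a seed |
| 3 | (interact and (second-bait hit or slim-annotated)) or (similar and slim-annotated) |
| 4 | interact and genetic-screen overlap (either screen) |
| 5 | interact and shared enriched process |
| 6 | interact or similar |
| 7 | slim-annotated |
| 8 | default |

Missing booleans count as false and a missing seed distance as
non-interacting, so the function is total; the tree is monotone (turning
any single evidence flag on never worsens the level), which is
property-tested. The complex-sharing and tag-binder flags are reported but
gate no level: no row of the 90-row reference table requires them.

Ranking is by level ascending; within a level, candidates absent from the
network come last, then degree ascending, then *descending* seed count at
the minimum distance, then protein id. The seed-count tie-break is the one
ordering consistent with both degree ties in the reference table
(degree-8 pair at level 3, degree-661 pair at level 7); an id-only
tie-break would invert both.

The packaged 90-row reference table is the normative fixture: the tree and
the ranking reproduce all 90 printed selection levels and the printed
order, and the test suite guards this exactly.

## Synthetic universe

The generator emulates the screen's data sources with planted ground
truth. Defaults: 250 proteins (1 bait, 4 seeds, 30 candidates, 215
background), ~80 ontology terms in a depth-5 is_a DAG with occasional
double parents, 12 complexes of 3–6 members, 10% predicted records, and
tier counts {0:2, 1:2, 2:3, 3:4, 4:3, 5:3, 6:3, 7:3, 8:7}. These sizes
keep every construction non-degenerate (all nine tiers populated, both
level-3 and level-4 variants present) while the whole pipeline runs in
well under a second.

Tiers are constructed adversarially minimal — each candidate satisfies
exactly its target rule and violates every higher rule — so recovery is
exact by construction rather than probabilistic, and the rule *order* is
what the end-to-end test exercises. Two constructions are analytic rather
than sampled: similarity ≥ 0.7 is forced by giving the candidate a single
direct term identical to a rare direct term of one seed (BMA ≥ 0.75 for
the Lin kernel regardless of corpus composition), and dissimilarity is
forced by annotating in branches disjoint from the seed branch (only
common ancestor is the root, similarity exactly 0). The rare shared term
is itself a slim descendant, so the similarity-plus-slim tier needs no
second annotation that would dilute the BMA. Predicted-method decoy
records connect non-interacting tiers directly to seeds: a broken
detection-method filter promotes those candidates and breaks recovery, so
the filter is load-bearing in the end-to-end test. The predicted-record
count is allocated exactly (count = round(fraction × total records)).

What the synthetic universe does *not* emulate: mass-spectrometry noise
and abundance effects, annotation bias toward well-studied proteins,
realistic interactome degree distributions at scale, or evidence-code
heterogeneity. Passing the recovery test therefore demonstrates that the
pipeline's logic composes correctly, not that the evidence layers are
well-powered on real data.

## Numerical choices and degenerate inputs

- Hypergeometric tails come from the log-space survival function; the
  k = 0 tail is exactly 1.
- Density of graphs with < 2 nodes is reported as 0 with a warning rather
  than raising, since empty subnetworks occur on filtered inputs.
- Sets and iteration orders are sorted before any randomized or
  order-sensitive step; the generator, the clustering and the pipeline are
  byte-reproducible given a seed (the generator writes config paths
  relative to the config file for this reason).
- Ids are opaque strings; ranking compares numeric ids numerically and
  falls back to lexicographic for non-numeric ids.
- MICA ties (equal IC) break lexicographically; this only affects which
  ancestor is reported, not the score.

## Known limitations

- The locally adjusted enrichment score is a published elim-style
  stand-in with the same stated intent as the score used in the
  motivating study, not a reimplementation of that tool's internals;
  outputs are labelled `local_p`.
- Absolute enrichment p-values on real corpora depend on database
  releases and are not reproduction targets; the oracle and calibration
  properties are.
- No evidence-code filtering, no part_of traversal, no cross-namespace
  reasoning, no confidence-weighted edges.
- The similarity-network composition printed in the motivating study
  depended on a historical external scoring server and is out of scope;
  threshold semantics and clustering behaviour are covered instead.
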