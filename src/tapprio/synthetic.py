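"""Self-contained synthetic universe with planted ground truth.

The generator emulates the data sources of a bait-centred interaction
screen: an is_a ontology DAG with annotations, an interactome mixing binary
records and multi-member complexes (with a controlled fraction of
"predicted" records that the filter must drop), a bait protein, a small
disease-seed set, candidate hit lists, external screen gene sets in a
foreign (fly-style) identifier space with an ortholog table, and a pathway
collection. Candidates are planted at known selection tiers: each tier-k
candidate is wired to satisfy exactly the level-k rule and to violate every
higher-priority rule, so end-to-end recovery of the truth table is exact by
construction, not probabilistic.

Key constructions
-----------------
* Functional similarity >= threshold is forced analytically: the candidate
  receives a single direct term identical to a rare direct term of one
  seed, which bounds the best-match average below by 0.75 for the Lin
  kernel (1 from the candidate side, >= (1+0)/2 from the seed side).
* Dissimilarity is forced by annotating non-similar tiers in ontology
  branches disjoint from the seed branch, so the only common ancestor is
  the root (information content 0, similarity 0).
* The rare shared term is a descendant of a slim term, so the
  similarity-plus-slim tier needs no second annotation that would dilute
  the best-match average.
* Predicted-method decoy records connect non-interacting tiers directly to
  seeds: if the detection-method filter fails, those candidates are
  promoted and recovery breaks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

ROOT = "GO:1000000"
SEED_BRANCH = "GO:1100000"
SEED_COMMON = "GO:1100001"
RARE_SHARED = "GO:1210001"  # seed0's rare term; child of the first slim term
SLIM_TERMS = [f"GO:120000{i}" for i in range(1, 6)]
SLIM_CHILDREN = {t: f"GO:121000{i}" for i, t in enumerate(SLIM_TERMS, start=1)}
COMPARISON_TERMS = [f"GO:130000{j}" for j in range(1, 7)]
COMPARISON_LEAVES = {t: f"GO:131000{j}" for j, t in enumerate(COMPARISON_TERMS, start=1)}

PREDICTED_METHODS = [
    "predicted by homology",
    "Interologs Mapping",
    "confirmational text mining pipeline",
]
CLEAN_METHODS = [
    "two hybrid",
    "anti tag coimmunoprecipitation",
    "pull down",
    "x-ray crystallography",
]


@dataclass
class SynthConfig:
    seed: int = 0
    n_proteins: int = 250
    n_terms: int = 80
    dag_depth: int = 5
    n_complexes: int = 12
    complex_size_range: tuple[int, int] = (3, 6)
    frac_predicted: float = 0.1
    n_seeds: int = 4
    n_candidates: int = 30
    tier_counts: dict[int, int] = field(
        default_factory=lambda: {0: 2, 1: 2, 2: 3, 3: 4, 4: 3, 5: 3, 6: 3, 7: 3, 8: 7}
    )
    funsim_threshold: float = 0.7

    def validate(self) -> None:
        if sum(self.tier_counts.values()) > self.n_candidates:
            raise ValueError("tier_counts sum exceeds n_candidates")
        if any(k < 0 or k > 8 for k in self.tier_counts):
            raise ValueError("tiers must be in 0..8")
        if any(v <= 0 for v in self.tier_counts.values()):
            raise ValueError("tier counts must be positive")
        if self.complex_size_range[0] < 3:
            raise ValueError("complexes need >= 3 members")
        if self.complex_size_range[1] > self.n_proteins:
            raise ValueError("complex size exceeds n_proteins")
        if self.n_seeds < 2:
            raise ValueError("need >= 2 seeds to plant the multi-seed tier")
        if not 0 <= self.frac_predicted < 1:
            raise ValueError("frac_predicted must be in [0, 1)")
        n_special = 1 + self.n_seeds + self.n_candidates
        if self.n_proteins < n_special + 20:
            raise ValueError("n_proteins too small for bait+seeds+candidates+background")
        if self.tier_counts.get(1) and self.n_seeds < 2:
            raise ValueError("tier 1 needs >= 2 seeds")


@dataclass
class SyntheticUniverse:
    """Paths of the written files plus the planted ground truth."""

    out_dir: Path
    ontology: Path
    annotations: Path
    interactions: Path
    orthologs: Path
    pathways: Path
    sets: Path
    config_file: Path
    truth: dict[str, int]  # candidate id -> intended selection level
    bait: str
    seeds: list[str]
    candidates: list[str]
    comparison_terms: list[str]
    slim_terms: list[str]


def generate_universe(cfg: SynthConfig, out_dir: str | Path) -> SyntheticUniverse:
    """Write the full synthetic universe under ``out_dir``.

    Byte-identical output for identical configs (all randomness flows from
    ``cfg.seed``; iteration orders are fixed).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bait = "9000"
    seeds = [f"8{i:03d}" for i in range(1, cfg.n_seeds + 1)]
    candidates = [f"7{i:03d}" for i in range(1, cfg.n_candidates + 1)]
    n_background = cfg.n_proteins - 1 - cfg.n_seeds - cfg.n_candidates
    background = [f"1{i:03d}" for i in range(1, n_background + 1)]

    terms = _build_dag(cfg, rng)
    annotations, truth_meta = _annotate(cfg, rng, bait, seeds, candidates, background)
    records, truth = _wire_network(
        cfg, rng, bait, seeds, candidates, background, truth_meta
    )
    fly_sets, ortho_rows = _external_screens(cfg, rng, truth_meta, background)

    paths = {
        "ontology": out / "ontology.obo",
        "annotations": out / "annotations.tsv",
        "interactions": out / "interactions.tsv",
        "orthologs": out / "orthologs.tsv",
        "pathways": out / "pathways.gmt.tsv",
        "sets": out / "sets.tsv",
        "config_file": out / "config.yaml",
    }
    _write_obo(paths["ontology"], terms)
    _write_annotations(paths["annotations"], annotations)
    _write_interactions(paths["interactions"], records)
    _write_tsv(paths["orthologs"], ortho_rows)
    _write_pathways(paths["pathways"], candidates, background, rng)
    _write_sets(paths["sets"], cfg, bait, seeds, candidates, truth_meta, fly_sets)
    _write_config(paths["config_file"], cfg, paths, bait)

    return SyntheticUniverse(
        out_dir=out,
        truth=truth,
        bait=bait,
        seeds=seeds,
        candidates=candidates,
        comparison_terms=list(COMPARISON_TERMS),
        slim_terms=list(SLIM_TERMS),
        **paths,
    )


# --- ontology ---------------------------------------------------------------


def _build_dag(cfg: SynthConfig, rng: np.random.Generator) -> list[dict]:
    """Term stanzas: fixed scaffold + random background branches.

    The scaffold keeps the seed branch, the slim branch (with one child per
    slim term; the first child doubles as the rare shared term), and the
    comparison branch (with one leaf each) in mutually disjoint subtrees so
    cross-branch similarity is exactly zero.
    """
    terms: list[dict] = [
        {"id": ROOT, "name": "biological_process", "parents": []},
        {"id": SEED_BRANCH, "name": "seed-related process", "parents": [ROOT]},
        {"id": SEED_COMMON, "name": "core seed process", "parents": [SEED_BRANCH]},
    ]
    for i, t in enumerate(SLIM_TERMS, start=1):
        terms.append({"id": t, "name": f"slim process {i}", "parents": [ROOT]})
        child = SLIM_CHILDREN[t]
        parents = [t]
        if child == RARE_SHARED:
            # the rare shared term also generalizes to the seed branch,
            # but its max-IC ancestor stays the slim term or itself
            parents = [t, SEED_BRANCH]
        terms.append({"id": child, "name": f"slim subprocess {i}", "parents": parents})
    for j, t in enumerate(COMPARISON_TERMS, start=1):
        terms.append({"id": t, "name": f"shared process {j}", "parents": [ROOT]})
        terms.append(
            {"id": COMPARISON_LEAVES[t], "name": f"shared subprocess {j}", "parents": [t]}
        )
    n_fixed = len(terms)
    n_bg = max(cfg.n_terms - n_fixed, 5)
    bg_ids = [f"GO:14{i:05d}" for i in range(1, n_bg + 1)]
    depths = {ROOT: 0}
    bg_pool = [ROOT]
    for tid in bg_ids:
        eligible = [t for t in bg_pool if depths[t] < cfg.dag_depth - 1]
        parent = eligible[int(rng.integers(len(eligible)))] if eligible else ROOT
        parents = [parent]
        # occasional second is_a parent: diamond structure, still acyclic
        # because parents are always earlier-created terms
        if len(bg_pool) > 3 and rng.random() < 0.15:
            other = bg_pool[int(rng.integers(len(bg_pool)))]
            if other not in parents:
                parents.append(other)
        terms.append({"id": tid, "name": f"background process {tid[-4:]}", "parents": parents})
        depths[tid] = depths[parent] + 1
        bg_pool.append(tid)
    # one obsolete stanza: loaders must drop it
    terms.append(
        {"id": "GO:1999999", "name": "withdrawn process", "parents": [ROOT], "obsolete": True}
    )
    return terms


def _bg_leaf_terms(cfg: SynthConfig) -> list[str]:
    n_fixed = 3 + 2 * len(SLIM_TERMS) + 2 * len(COMPARISON_TERMS)
    n_bg = max(cfg.n_terms - n_fixed, 5)
    return [f"GO:14{i:05d}" for i in range(1, n_bg + 1)]


# --- annotations & tier metadata -------------------------------------------


def _annotate(cfg, rng, bait, seeds, candidates, background):
    """Assign direct annotations and fix each candidate's tier and variant.

    Returns (protein -> direct terms, tier metadata). Tier metadata maps
    candidate -> dict(tier, variant) and also records which candidates need
    seed edges, bait edges, screen membership etc.
    """
    bg_terms = _bg_leaf_terms(cfg)

    def bg_sample(k: int) -> list[str]:
        idx = rng.choice(len(bg_terms), size=min(k, len(bg_terms)), replace=False)
        return [bg_terms[i] for i in sorted(idx)]

    annotations: dict[str, list[str]] = {}
    annotations[bait] = [SEED_COMMON] + bg_sample(2)
    for i, s in enumerate(seeds):
        annotations[s] = [SEED_COMMON, RARE_SHARED] if i == 0 else [SEED_COMMON]
    for b in background:
        terms = bg_sample(int(rng.integers(1, 4)))
        # broad annotation keeps the comparison parents generic (low IC)
        if rng.random() < 0.4:
            terms.append(COMPARISON_TERMS[int(rng.integers(len(COMPARISON_TERMS)))])
        annotations[b] = terms

    meta: dict[str, dict] = {}
    ordered_tiers = [t for t in sorted(cfg.tier_counts) for _ in range(cfg.tier_counts[t])]
    # unallocated candidates default to the bottom tier
    ordered_tiers += [8] * (cfg.n_candidates - len(ordered_tiers))
    slim_only = [c for t, c in SLIM_CHILDREN.items() if c != RARE_SHARED]
    per_tier_counter: dict[int, int] = {}
    for cand, tier in zip(candidates, ordered_tiers):
        k = per_tier_counter.get(tier, 0)
        per_tier_counter[tier] = k + 1
        variant = ""
        if tier == 0:
            annotations[cand] = bg_sample(2)
        elif tier == 1:
            annotations[cand] = bg_sample(2)
        elif tier == 2:
            annotations[cand] = [RARE_SHARED]
        elif tier == 3:
            variant = "interact_second_bait" if k % 2 else "funsim_slim"
            if variant == "funsim_slim":
                annotations[cand] = [RARE_SHARED]
            else:
                annotations[cand] = bg_sample(2)
        elif tier == 4:
            variant = "parkin_gs" if k % 2 == 0 else "pink1_gs"
            annotations[cand] = bg_sample(2)
        elif tier == 5:
            leaf = COMPARISON_LEAVES[COMPARISON_TERMS[k % len(COMPARISON_TERMS)]]
            annotations[cand] = [leaf]
        elif tier == 6:
            annotations[cand] = bg_sample(2)
        elif tier == 7:
            annotations[cand] = [slim_only[k % len(slim_only)]]
        else:
            annotations[cand] = bg_sample(2)
        meta[cand] = {"tier": tier, "variant": variant}
    return annotations, meta


# --- interactome ------------------------------------------------------------


def _wire_network(cfg, rng, bait, seeds, candidates, background, meta):
    """Build interaction records implementing each candidate's tier.

    Returns (records, truth). Records are dicts with members/kind/method.
    """
    records: list[dict] = []
    rid = [0]

    def add(members, kind, method=None):
        rid[0] += 1
        if method is None:
            method = CLEAN_METHODS[int(rng.integers(len(CLEAN_METHODS)))]
        records.append(
            {
                "id": f"r{rid[0]:05d}",
                "members": list(members),
                "kind": kind,
                "method": method,
            }
        )

    # scaffold: the bait interacts with every seed (so planted seed
    # interactors sit at bait-distance 2, never 1)
    for s in seeds:
        add([bait, s], "binary")
    # background backbone: sparse preferential-attachment-ish chain
    for i, b in enumerate(background):
        if i == 0:
            continue
        j = int(rng.integers(max(0, i - 10), i))
        add([background[j], b], "binary")
        if rng.random() < 0.3:
            j2 = int(rng.integers(i))
            if background[j2] != background[j]:
                add([background[j2], b], "binary")
    # a few background proteins touch seeds (never candidates to seeds)
    for s in seeds:
        for b in rng.choice(len(background), size=3, replace=False):
            add([s, background[int(b)]], "binary")

    truth: dict[str, int] = {}
    seed_cycle = 0
    decoy_candidates: list[str] = []
    for cand in candidates:
        tier = meta[cand]["tier"]
        variant = meta[cand]["variant"]
        truth[cand] = tier
        # anchor every candidate in the network via background edges
        for b in rng.choice(len(background), size=2, replace=False):
            add([cand, background[int(b)]], "binary")
        if tier == 0:
            add([cand, bait], "binary")
        elif tier == 1:
            add([cand, seeds[0]], "binary")
            add([cand, seeds[1]], "binary")
        elif tier == 2:
            add([cand, seeds[0]], "binary")
        elif tier == 3 and variant == "interact_second_bait":
            seed_cycle = (seed_cycle + 1) % len(seeds)
            add([cand, seeds[seed_cycle]], "binary")
        elif tier in (4, 5, 6):
            seed_cycle = (seed_cycle + 1) % len(seeds)
            add([cand, seeds[seed_cycle]], "binary")
        elif tier in (7, 8) or variant == "funsim_slim":
            decoy_candidates.append(cand)

    # complexes among background; one complex deliberately contains two
    # bottom-tier candidates so they share complex evidence (not_complex
    # false) without affecting any level
    tier8 = [c for c in candidates if truth[c] == 8]
    for ci in range(cfg.n_complexes):
        k = int(rng.integers(cfg.complex_size_range[0], cfg.complex_size_range[1] + 1))
        members = [background[int(i)] for i in rng.choice(len(background), size=k, replace=False)]
        if ci == 0 and len(tier8) >= 2:
            members = members[:-2] + tier8[:2] if k > 2 else members + tier8[:2]
        add(members, "complex")

    # predicted decoys: candidate-seed edges that must be filtered away,
    # padded with background pairs to hit the exact predicted fraction
    n_clean = len(records)
    n_pred = round(cfg.frac_predicted * n_clean / (1.0 - cfg.frac_predicted))
    while n_pred != round(cfg.frac_predicted * (n_clean + n_pred)):
        n_pred += 1 if n_pred < cfg.frac_predicted * (n_clean + n_pred) else -1
    made = 0
    for cand in decoy_candidates:
        if made >= n_pred:
            break
        s = seeds[made % len(seeds)]
        add([cand, s], "binary", method=PREDICTED_METHODS[made % len(PREDICTED_METHODS)])
        made += 1
    while made < n_pred:
        i, j = rng.choice(len(background), size=2, replace=False)
        add(
            [background[int(i)], background[int(j)]],
            "binary",
            method=PREDICTED_METHODS[made % len(PREDICTED_METHODS)],
        )
        made += 1
    return records, truth


# --- external evidence ------------------------------------------------------


def _external_screens(cfg, rng, meta, background):
    """Fly-style screen gene sets plus the fly->human ortholog table."""
    parkin_targets = [c for c, m in meta.items() if m["variant"] == "parkin_gs"]
    pink1_targets = [c for c, m in meta.items() if m["variant"] == "pink1_gs"]
    ortho_rows: list[tuple[str, str]] = []
    fly_sets: dict[str, list[str]] = {"ParkinGS_fly": [], "Pink1GS_fly": []}
    fly_n = 0

    def fly_id() -> str:
        nonlocal fly_n
        fly_n += 1
        return f"FBgn{fly_n:06d}"

    for label, targets in (("ParkinGS_fly", parkin_targets), ("Pink1GS_fly", pink1_targets)):
        for hum in targets:
            f = fly_id()
            fly_sets[label].append(f)
            ortho_rows.append((f, hum))
            # many-to-many: some fly genes map to an extra background human gene
            if rng.random() < 0.5:
                ortho_rows.append((f, background[int(rng.integers(len(background)))]))
        # screen noise: fly genes mapping only to background proteins
        for _ in range(5):
            f = fly_id()
            fly_sets[label].append(f)
            ortho_rows.append((f, background[int(rng.integers(len(background)))]))
        # and one unmappable fly gene
        fly_sets[label].append(fly_id())
    return fly_sets, ortho_rows


# --- writers ----------------------------------------------------------------


def _write_obo(path: Path, terms: list[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-bp\n")
        for t in terms:
            fh.write("\n[Term]\n")
            fh.write(f"id: {t['id']}\nname: {t['name']}\n")
            fh.write("namespace: biological_process\n")
            for p in t["parents"]:
                fh.write(f"is_a: {p}\n")
            if t.get("obsolete"):
                fh.write("is_obsolete: true\n")


def _write_annotations(path: Path, annotations: dict[str, list[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein_id\tterm_id\tevidence\n")
        for protein in sorted(annotations):
            for term in sorted(set(annotations[protein])):
                fh.write(f"{protein}\t{term}\tIEA\n")


def _write_interactions(path: Path, records: list[dict]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# record_id\tmembers\tkind\tdetection_method\tsource\n")
        for r in records:
            fh.write(
                f"{r['id']}\t{';'.join(r['members'])}\t{r['kind']}"
                f"\t{r['method']}\tsynthdb\n"
            )


def _write_tsv(path: Path, rows: list[tuple[str, str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def _write_pathways(path: Path, candidates, background, rng) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        enriched = sorted(candidates)[: max(5, len(candidates) // 2)]
        pad = [background[int(i)] for i in rng.choice(len(background), size=5, replace=False)]
        fh.write("hit_pathway\tplanted enriched pathway\t" + "\t".join(enriched + pad) + "\n")
        for p in range(3):
            members = sorted(
                background[int(i)]
                for i in rng.choice(len(background), size=12, replace=False)
            )
            fh.write(f"bg_pathway_{p}\tbackground pathway\t" + "\t".join(members) + "\n")


def _write_sets(path: Path, cfg, bait, seeds, candidates, meta, fly_sets) -> None:
    second_bait_hits = sorted(
        c for c, m in meta.items() if m["variant"] == "interact_second_bait"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# set_label\tprotein_id\n")
        fh.write(f"Bait\t{bait}\n")
        for s in seeds:
            fh.write(f"Seeds\t{s}\n")
        for c in candidates:
            fh.write(f"Candidates\t{c}\n")
        for c in second_bait_hits:
            fh.write(f"SecondBaitTAP\t{c}\n")
        for label, members in fly_sets.items():
            for m in members:
                fh.write(f"{label}\t{m}\n")


def _write_config(path: Path, cfg: SynthConfig, paths: dict, bait: str) -> None:
    # paths are written relative to the config file, so regenerating the
    # same universe in a different directory is byte-identical
    config = {
        "ontology": paths["ontology"].name,
        "annotations": paths["annotations"].name,
        "interactions": paths["interactions"].name,
        "orthologs": paths["orthologs"].name,
        "pathways": paths["pathways"].name,
        "sets": paths["sets"].name,
        "bait_id": bait,
        "funsim_threshold": cfg.funsim_threshold,
        "classic_cutoff": 1e-3,
        "local_cutoff": 0.01,
        "cluster_p": 0.05,
        "comparison_terms": list(COMPARISON_TERMS),
        "slim_terms": list(SLIM_TERMS),
        "seed": cfg.seed,
        "generator": dataclasses.asdict(cfg),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def write_truth_table(universe: SyntheticUniverse, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# candidate_id\tintended_level\n")
        for cand in sorted(universe.truth):
            fh.write(f"{cand}\t{universe.truth[cand]}\n")


def planted_module_graph(
    n_modules: int = 4,
    module_size: int = 6,
    n_noise_nodes: int = 6,
    seed: int = 0,
):
    """A weighted similarity-style graph with planted dense modules.

    In-module edges are complete with high weights (0.8–1.0); modules are
    joined to a sparse noise background by low-weight edges (0.1–0.3).
    Returns (graph, list of planted member sets).
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    planted = []
    node = 0
    for _ in range(n_modules):
        members = [f"n{node + i:03d}" for i in range(module_size)]
        node += module_size
        planted.append(set(members))
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                g.add_edge(a, b, weight=float(0.8 + 0.2 * rng.random()))
    noise = [f"x{j:03d}" for j in range(n_noise_nodes)]
    for j, x in enumerate(noise):
        g.add_node(x)
        targets = rng.choice(node, size=2, replace=False)
        for t in targets:
            g.add_edge(x, f"n{int(t):03d}", weight=float(0.1 + 0.2 * rng.random()))
    return g, planted
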