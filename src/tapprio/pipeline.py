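"""End-to-end pipeline: inputs -> ranked candidate table.

Stages mirror the analysis flow of a bait-centred screen follow-up:

1. load named protein sets (candidates, seeds, bait, second-bait hits,
   external screens) and the ortholog table;
2. build the filtered interactome from binary + complex records, derive the
   candidate/seed shortest-path subnetwork, compute network features;
3. ontology + annotations -> enrichment (classic/local) for the candidate
   and disease-related sets, shared-process flags, slim flags;
4. semantic similarity of candidates to seeds, similarity network,
   overlapping clusters;
5. external-screen ortholog mapping, overlap tests, evidence flags;
6. feature assembly, decision tree, ranked table; everything written to an
   output directory with a manifest echoing the configuration.

All stage functions are importable; :func:`run_pipeline` is what the CLI
(and the examples) call.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Any

import yaml

from . import enrichment as enr
from . import funsim as fs
from . import interactome as inet
from . import ontology as onto
from . import overlap as ov
from . import prioritize as prio
from . import registry as reg

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


REQUIRED_PATHS = ("ontology", "annotations", "interactions", "sets")


@dataclass
class PipelineConfig:
    ontology: Path
    annotations: Path
    interactions: Path
    sets: Path
    orthologs: Path | None = None
    pathways: Path | None = None
    bait_id: str = ""
    funsim_threshold: float = 0.7
    classic_cutoff: float = 1e-3
    local_cutoff: float = 0.01
    cluster_p: float = 0.05
    comparison_terms: list[str] = dataclass_field(default_factory=list)
    slim_terms: list[str] = dataclass_field(default_factory=list)
    universe_sizes: dict[str, int] = dataclass_field(default_factory=dict)
    seed: int = 0
    n_permutations: int = 200

    @classmethod
    def from_mapping(cls, raw: dict[str, Any]) -> "PipelineConfig":
        missing = [k for k in REQUIRED_PATHS if not raw.get(k)]
        if missing:
            raise ConfigError(f"missing required config fields: {', '.join(missing)}")
        known = {f.name for f in cls.__dataclass_fields__.values()}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("ontology", "annotations", "interactions", "sets", "orthologs", "pathways"):
            if kwargs.get(key):
                kwargs[key] = Path(kwargs[key])
        cfg = cls(**kwargs)
        for thr in ("funsim_threshold", "classic_cutoff", "local_cutoff", "cluster_p"):
            v = getattr(cfg, thr)
            if not 0 < v <= 1:
                raise ConfigError(f"{thr} must be in (0, 1], got {v}")
        for key in REQUIRED_PATHS:
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise ConfigError(f"config field {key!r}: path does not exist: {p}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        # relative input paths are resolved against the config file
        base = Path(path).parent
        for key in ("ontology", "annotations", "interactions", "sets", "orthologs", "pathways"):
            if raw.get(key) and not Path(raw[key]).is_absolute():
                raw[key] = str(base / raw[key])
        return cls.from_mapping(raw)


@dataclass
class PipelineResult:
    out_dir: Path
    features: list[prio.CandidateFeatures]
    ranked: list[tuple[int, prio.CandidateFeatures, prio.SelectionLevel]]
    levels: dict[str, int]
    network_stats: dict
    spnet_stats: dict
    clusters: fs.ClusterResult | None
    overlap_tests: list[ov.OverlapTest]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception:
                log.error("stage %s: failed", name)
                raise
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


@_stage("datasets")
def load_inputs(cfg: PipelineConfig) -> dict:
    registry = reg.load_named_sets(cfg.sets)
    for label in ("Candidates", "Seeds"):
        if label not in registry:
            raise ConfigError(f"sets file must define a {label!r} set")
    bait = cfg.bait_id or (
        sorted(registry["Bait"].ids)[0] if "Bait" in registry else ""
    )
    if not bait:
        raise ConfigError("no bait id: set bait_id or provide a 'Bait' set")
    ortho = reg.read_id_map(cfg.orthologs) if cfg.orthologs else {}
    return {
        "registry": registry,
        "bait": bait,
        "candidates": sorted(registry["Candidates"].ids),
        "seeds": sorted(registry["Seeds"].ids),
        "orthologs": ortho,
    }


@_stage("network")
def network_stage(cfg: PipelineConfig, inputs: dict) -> dict:
    records = inet.read_interactions(cfg.interactions)
    records = inet.filter_predicted(records)
    hnet = inet.build_network(inet.expand_complexes(records))
    spnet = inet.extract_subnetwork(
        hnet,
        inputs["candidates"],
        inputs["seeds"] + [inputs["bait"]],
    )
    features = inet.candidate_network_features(
        spnet,
        inputs["candidates"],
        inputs["bait"],
        inputs["seeds"],
        degree_net=hnet,
    )
    return {
        "hnet": hnet,
        "spnet": spnet,
        "network_features": features,
        "hnet_stats": inet.network_stats(hnet),
        "spnet_stats": inet.network_stats(spnet),
    }


@_stage("enrichment")
def enrichment_stage(cfg: PipelineConfig, inputs: dict) -> dict:
    dag = onto.load_ontology(cfg.ontology)
    direct = onto.read_annotations(cfg.annotations)
    annotations = onto.propagate(dag, direct)
    cand_results = enr.enrich(
        inputs["candidates"], dag, annotations, local_cutoff=cfg.local_cutoff
    )
    related = sorted(set(inputs["seeds"]) | {inputs["bait"]})
    related_results = enr.enrich(
        related, dag, annotations, local_cutoff=cfg.local_cutoff
    )
    gocomp = enr.shared_term_flags(
        cand_results,
        related_results,
        dag,
        annotations,
        inputs["candidates"],
        cutoff=cfg.classic_cutoff,
        comparison_terms=cfg.comparison_terms or None,
    )
    goslim = (
        onto.slim_membership(annotations, cfg.slim_terms, dag)
        if cfg.slim_terms
        else {}
    )
    pathways = {}
    if cfg.pathways:
        collection = enr.read_gene_set_collection(cfg.pathways)
        pathways = {
            "results": enr.gene_set_enrichment(
                inputs["candidates"], collection, annotations.proteins()
            )
        }
    return {
        "dag": dag,
        "annotations": annotations,
        "cand_enrichment": cand_results,
        "related_enrichment": related_results,
        "gocomp": gocomp,
        "goslim": {c: goslim.get(c, False) for c in inputs["candidates"]},
        "pathways": pathways,
    }


@_stage("funsim")
def funsim_stage(cfg: PipelineConfig, inputs: dict, enriched: dict) -> dict:
    dag, annotations = enriched["dag"], enriched["annotations"]
    ic = fs.information_content(annotations, dag)
    proteins = sorted(set(inputs["candidates"]) | set(inputs["seeds"]))
    scores = fs.pairwise_similarity(proteins, annotations, dag, ic)
    seed_set = set(inputs["seeds"])
    funsim_seed = {}
    for c in inputs["candidates"]:
        best = max(
            (
                s
                for pair, s in scores.items()
                if c in pair and (pair - {c}) & seed_set
            ),
            default=None,
        )
        funsim_seed[c] = best is not None and best >= cfg.funsim_threshold
    graph = fs.build_funsim_network(proteins, scores, cfg.funsim_threshold)
    clusters = fs.find_clusters(
        graph, n_permutations=cfg.n_permutations, seed=cfg.seed or 17
    )
    return {
        "ic": ic,
        "scores": scores,
        "funsim_seed": funsim_seed,
        "graph": graph,
        "clusters": clusters,
    }


@_stage("overlap")
def overlap_stage(cfg: PipelineConfig, inputs: dict, network: dict) -> dict:
    registry = inputs["registry"]
    candidates = set(inputs["candidates"])
    flag_sets: dict[str, set[str]] = {}
    tests: list[ov.OverlapTest] = []
    universe = set(network["hnet"].nodes) | candidates
    screens = {
        "parkin_gs": "ParkinGS_fly",
        "pink1_gs": "Pink1GS_fly",
    }
    for flag, label in screens.items():
        if label not in registry:
            flag_sets[flag] = set()
            continue
        mapped, _ = ov.map_orthologs(registry[label].ids, inputs["orthologs"])
        flag_sets[flag] = mapped
        tests.append(
            ov.overlap_test(candidates, mapped, universe, universe_label="interactome")
        )
    flag_sets["pink1tap"] = (
        registry["SecondBaitTAP"].ids if "SecondBaitTAP" in registry else set()
    )
    # purification-tag artifact flag: interactome neighbors of the tag binder
    calmodulin = sorted(registry["TagBinder"].ids)[0] if "TagBinder" in registry else None
    flag_sets["calmodulin_ip"] = (
        set(network["hnet"][calmodulin])
        if calmodulin and calmodulin in network["hnet"]
        else set()
    )
    flags = ov.flag_candidates(candidates, flag_sets)
    return {"flags": flags, "tests": tests}


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Execute all stages and write the output directory.

    Outputs: ranked feature table, enrichment tables, similarity network,
    clusters, overlap tests, run log and a manifest echoing the config;
    reruns on identical inputs are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(cfg)
    network = network_stage(cfg, inputs)
    enriched = enrichment_stage(cfg, inputs)
    similarity = funsim_stage(cfg, inputs, enriched)
    overlaps = overlap_stage(cfg, inputs, network)

    features = prio.build_features(
        inputs["candidates"],
        network=network["network_features"],
        gocomp=enriched["gocomp"],
        funsim_seed=similarity["funsim_seed"],
        goslim=enriched["goslim"],
        flags=overlaps["flags"],
    )
    ranked = prio.rank_table(features)
    levels = {f.protein_id: lvl.level for _, f, lvl in ranked}

    prio.write_feature_table(ranked, out / "ranked_candidates.tsv")
    enr.write_enrichment_table(enriched["cand_enrichment"], out / "enrichment_candidates.tsv")
    enr.write_enrichment_table(enriched["related_enrichment"], out / "enrichment_related.tsv")
    if enriched["pathways"]:
        enr.write_enrichment_table(
            enriched["pathways"]["results"], out / "enrichment_pathways.tsv"
        )
    fs.write_similarity_matrix(similarity["scores"], out / "funsim_scores.tsv")
    fs.write_clusters(similarity["clusters"], out / "funsim_clusters.tsv")
    ov.write_overlap_tests(overlaps["tests"], out / "overlap_tests.tsv")
    inet.write_edge_list(network["spnet"], out / "spnet_edges.tsv")

    manifest = {
        "config": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in vars(cfg).items()
        },
        "n_candidates": len(inputs["candidates"]),
        "hnet": {k: network["hnet_stats"][k] for k in ("n_nodes", "n_edges", "density")},
        "spnet": {k: network["spnet_stats"][k] for k in ("n_nodes", "n_edges", "density")},
        "outputs": {},
    }
    for f in sorted(out.glob("*.tsv")):
        manifest["outputs"][f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        out_dir=out,
        features=features,
        ranked=ranked,
        levels=levels,
        network_stats=network["hnet_stats"],
        spnet_stats=network["spnet_stats"],
        clusters=similarity["clusters"],
        overlap_tests=overlaps["tests"],
    )
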