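"""Feature assembly, the 9-tier selection-level decision tree, and ranking.

Every candidate from the screen gets one feature row combining network
evidence (distance to the bait, minimum distance to the disease-seed set
and how many seeds attain it, degree, complex sharing), functional evidence
(shared enriched processes, semantic similarity to a seed, slim-term
annotation) and external-screen evidence. A first-match decision tree maps
the row to a selection level from 0 (highest priority: a reported bait
interactor) to 8 (no supporting evidence); the ranked table orders
candidates by level, then ascending degree (fewer interactions = more
specific evidence), proteins absent from the network last within a level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .interactome import NetworkFeatures

#: Feature-table columns, in export order.
TABLE_COLUMNS = [
    "Rank",
    "Entrez Gene ID",
    "HGNC Symbol",
    "Parkin ND",
    "MonogenicPD ND",
    "MonogenicPD #ND",
    "iMonogenicPD",
    "Not Complex",
    "Pink1 TAP",
    "HNet Degree",
    "GOComp",
    "FunSim MonogenicPD",
    "GOSlimPD",
    "ParkinGS",
    "Pink1GS",
    "CalmodulinIP",
    "Selection Level",
]

MISSING = "–"  # en-dash, the printed missing/false marker


@dataclass
class CandidateFeatures:
    """One candidate's complete feature vector (one table row)."""

    protein_id: str
    symbol: str = ""
    parkin_nd: int | None = None
    seed_nd: int | None = None
    seed_nd_count: int | None = None
    seed_interactors: set[str] = field(default_factory=set)
    degree: int | None = None
    not_complex: bool | None = None
    known_bait_interactor: bool = False
    pink1tap: bool = False
    gocomp: bool = False
    funsim_seed: bool = False
    goslim: bool = False
    parkin_gs: bool = False
    pink1_gs: bool = False
    calmodulin_ip: bool = False

    @property
    def in_network(self) -> bool:
        return self.degree is not None

    @property
    def interacts_with_seed(self) -> bool:
        return self.seed_nd == 1


@dataclass(frozen=True)
class SelectionLevel:
    level: int
    matched_rule: str


def assign_selection_level(f: CandidateFeatures) -> SelectionLevel:
    """First-match decision tree over the feature vector.

    Missing booleans count as false and a missing seed distance as
    non-interacting, so the function is total. The rule order encodes the
    evidence hierarchy: reported bait interaction beats multi-seed
    interaction beats interaction+similarity, and so on down to slim-term
    annotation alone.
    """
    interact = f.interacts_with_seed
    if f.known_bait_interactor or f.parkin_nd == 0:
        return SelectionLevel(0, "reported bait interactor")
    if interact and (f.seed_nd_count or 0) >= 2:
        return SelectionLevel(1, "interacts with >=2 seed proteins")
    if interact and f.funsim_seed:
        return SelectionLevel(2, "interacts with and functionally similar to a seed")
    if (interact and (f.pink1tap or f.goslim)) or (f.funsim_seed and f.goslim):
        return SelectionLevel(3, "interaction or similarity plus second-bait/slim support")
    if interact and (f.parkin_gs or f.pink1_gs):
        return SelectionLevel(4, "interacts with a seed and genetic-screen support")
    if interact and f.gocomp:
        return SelectionLevel(5, "interacts with a seed and shared enriched process")
    if interact or f.funsim_seed:
        return SelectionLevel(6, "interacts with or functionally similar to a seed")
    if f.goslim:
        return SelectionLevel(7, "annotated to a disease slim process")
    return SelectionLevel(8, "no supporting evidence")


def build_features(
    candidates: Iterable[str],
    network: Mapping[str, NetworkFeatures] | None = None,
    known_bait_interactors: Iterable[str] = (),
    gocomp: Mapping[str, bool] | None = None,
    funsim_seed: Mapping[str, bool] | None = None,
    goslim: Mapping[str, bool] | None = None,
    flags: Mapping[str, Mapping[str, bool]] | None = None,
    symbols: Mapping[str, str] | None = None,
) -> list[CandidateFeatures]:
    """Assemble feature rows from the upstream module outputs.

    ``flags`` carries the external-evidence booleans under the labels
    ``pink1tap``, ``parkin_gs``, ``pink1_gs`` and ``calmodulin_ip``.
    Candidates absent from every upstream result yield an all-missing row.
    """
    known = set(known_bait_interactors)
    rows = []
    for c in sorted(set(candidates)):
        nf = (network or {}).get(c, NetworkFeatures())
        cflags = (flags or {}).get(c, {})
        rows.append(
            CandidateFeatures(
                protein_id=c,
                symbol=(symbols or {}).get(c, ""),
                parkin_nd=nf.parkin_nd,
                seed_nd=nf.seed_nd,
                seed_nd_count=nf.seed_nd_count,
                seed_interactors=set(nf.seed_interactors),
                degree=nf.degree,
                not_complex=nf.not_complex,
                known_bait_interactor=(
                    c in known or (nf.parkin_nd is not None and nf.parkin_nd <= 1)
                ),
                pink1tap=cflags.get("pink1tap", False),
                gocomp=(gocomp or {}).get(c, False),
                funsim_seed=(funsim_seed or {}).get(c, False),
                goslim=(goslim or {}).get(c, False),
                parkin_gs=cflags.get("parkin_gs", False),
                pink1_gs=cflags.get("pink1_gs", False),
                calmodulin_ip=cflags.get("calmodulin_ip", False),
            )
        )
    return rows


def _id_sort_key(protein_id: str):
    return (0, int(protein_id), "") if protein_id.isdigit() else (1, 0, protein_id)


def rank_table(
    features: Sequence[CandidateFeatures],
) -> list[tuple[int, CandidateFeatures, SelectionLevel]]:
    """Rank candidates: (rank, features, level), rank starting at 1.

    Order: selection level ascending; within a level, candidates absent
    from the network come last; then degree ascending (few, specific
    interactions first), more seeds at the minimum distance first, and
    finally protein id for full determinism.
    """
    scored = [(f, assign_selection_level(f)) for f in features]
    scored.sort(
        key=lambda fl: (
            fl[1].level,
            0 if fl[0].in_network else 1,
            fl[0].degree if fl[0].degree is not None else 0,
            -(fl[0].seed_nd_count or 0),
            _id_sort_key(fl[0].protein_id),
        )
    )
    return [(i, f, lvl) for i, (f, lvl) in enumerate(scored, start=1)]


def _fmt_int(v: int | None) -> str:
    return MISSING if v is None else str(v)


def _fmt_bool(v: bool | None) -> str:
    return "true" if v else MISSING


def write_feature_table(
    ranked: Sequence[tuple[int, CandidateFeatures, SelectionLevel]],
    path: str | Path,
    symbols_of_seeds: Mapping[str, str] | None = None,
) -> None:
    """Write the ranked feature table in the printed column order.

    Missing values and false flags are both rendered as the en-dash, and
    the seed-interactor column lists symbols (falling back to ids) or "0".
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for rank, f, lvl in ranked:
            seeds = sorted(
                (symbols_of_seeds or {}).get(s, s) for s in f.seed_interactors
            )
            fh.write(
                "\t".join(
                    [
                        str(rank),
                        f.protein_id,
                        f.symbol,
                        _fmt_int(f.parkin_nd),
                        _fmt_int(f.seed_nd),
                        _fmt_int(f.seed_nd_count),
                        ", ".join(seeds) if seeds else "0",
                        _fmt_bool(f.not_complex and f.in_network),
                        _fmt_bool(f.pink1tap),
                        _fmt_int(f.degree),
                        _fmt_bool(f.gocomp),
                        _fmt_bool(f.funsim_seed),
                        _fmt_bool(f.goslim),
                        _fmt_bool(f.parkin_gs),
                        _fmt_bool(f.pink1_gs),
                        _fmt_bool(f.calmodulin_ip),
                        str(lvl.level),
                    ]
                )
                + "\n"
            )


def read_feature_table(path: str | Path) -> list[dict]:
    """Read a feature table (the packaged gold standard or an export).

    Returns one dict per row with parsed fields plus the printed rank and
    selection level, preserving file order.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for raw in fh:
            if not raw.strip():
                continue
            cells = raw.rstrip("\n").split("\t")

            def cell(name: str) -> str:
                return cells[idx[name]]

            def as_int(name: str) -> int | None:
                v = cell(name)
                return None if v in (MISSING, "-", "") else int(v)

            def as_bool(name: str) -> bool:
                return cell(name) == "true"

            interactors = cell("iMonogenicPD")
            seed_list = (
                [] if interactors in ("0", "", MISSING)
                else [s.strip() for s in interactors.split(",")]
            )
            rows.append(
                {
                    "rank": int(cell("Rank")),
                    "printed_level": int(cell("Selection Level")),
                    "features": CandidateFeatures(
                        protein_id=cell("Entrez Gene ID"),
                        symbol=cell("HGNC Symbol"),
                        parkin_nd=as_int("Parkin ND"),
                        seed_nd=as_int("MonogenicPD ND"),
                        seed_nd_count=as_int("MonogenicPD #ND"),
                        seed_interactors=set(seed_list),
                        degree=as_int("HNet Degree"),
                        not_complex=as_bool("Not Complex"),
                        known_bait_interactor=(
                            as_int("Parkin ND") is not None
                            and as_int("Parkin ND") <= 1
                        ),
                        pink1tap=as_bool("Pink1 TAP"),
                        gocomp=as_bool("GOComp"),
                        funsim_seed=as_bool("FunSim MonogenicPD"),
                        goslim=as_bool("GOSlimPD"),
                        parkin_gs=as_bool("ParkinGS"),
                        pink1_gs=as_bool("Pink1GS"),
                        calmodulin_ip=as_bool("CalmodulinIP"),
                    ),
                }
            )
    return rows
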