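"""Named protein sets: loading, identifier mapping, and set algebra.

All cross-dataset comparisons in the pipeline are made on a single opaque
identifier space (Entrez-style numeric strings in the motivating screen).
Identifier translation (e.g. fly -> human orthologs, UniProt -> Entrez) is
frozen into static two-column tables supplied as input; no remote resolution
is ever attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A tabular input file violates the expected dialect."""


@dataclass(frozen=True)
class ProteinRef:
    """A protein/gene reference; equality and hashing on ``id`` only."""

    id: str
    symbol: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRef id must be non-empty")


@dataclass
class NamedSet:
    """A labelled protein set (one row block of a dataset table)."""

    label: str
    members: set[ProteinRef]
    description: str = ""

    def __len__(self) -> int:
        return len(self.members)

    @property
    def ids(self) -> set[str]:
        return {p.id for p in self.members}


class SetRegistry:
    """Ordered mapping of label -> NamedSet with unique labels."""

    def __init__(self) -> None:
        self._sets: dict[str, NamedSet] = {}

    def add(self, named: NamedSet) -> None:
        if named.label in self._sets:
            raise KeyError(f"duplicate set label: {named.label!r}")
        self._sets[named.label] = named

    def __getitem__(self, label: str) -> NamedSet:
        try:
            return self._sets[label]
        except KeyError:
            raise KeyError(f"unknown set label: {label!r}") from None

    def __contains__(self, label: str) -> bool:
        return label in self._sets

    def __iter__(self):
        return iter(self._sets.values())

    def labels(self) -> list[str]:
        return list(self._sets)


def read_id_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column ``from_id TAB to_id`` table into a many-to-many map."""
    mapping: dict[str, set[str]] = {}
    for fields, _ in _iter_rows(path, min_cols=2):
        mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping


def apply_id_map(
    members: Iterable[ProteinRef], id_map: Mapping[str, set[str]]
) -> tuple[set[ProteinRef], set[str]]:
    """Map a protein set through a many-to-many id table.

    A source id mapping to k targets contributes all k targets. Unmappable
    ids are retained verbatim (and returned separately so callers can log
    them); dropping them would silently shrink the printed set sizes.
    """
    mapped: set[ProteinRef] = set()
    unmapped: set[str] = set()
    for p in members:
        targets = id_map.get(p.id)
        if targets:
            mapped.update(ProteinRef(t) for t in sorted(targets))
        else:
            mapped.add(p)
            unmapped.add(p.id)
    return mapped, unmapped


def _iter_rows(path: str | Path, min_cols: int):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {min_cols} tab-separated "
                    f"columns, got {len(fields)}"
                )
            yield fields, lineno


def load_named_sets(
    path: str | Path, id_map: Mapping[str, set[str]] | None = None
) -> SetRegistry:
    """Load a ``set_label TAB protein_id [TAB symbol]`` table into a registry.

    Duplicate (label, id) rows collapse to one member. With ``id_map``,
    every set is pushed through :func:`apply_id_map` after loading.
    """
    raw: dict[str, set[ProteinRef]] = {}
    for fields, _ in _iter_rows(path, min_cols=2):
        label, pid = fields[0], fields[1]
        symbol = fields[2] if len(fields) > 2 and fields[2] else None
        raw.setdefault(label, set()).add(ProteinRef(pid, symbol))
    if not raw:
        log.warning("no set rows found in %s; registry is empty", path)
    registry = SetRegistry()
    for label, members in raw.items():
        if id_map is not None:
            members, unmapped = apply_id_map(members, id_map)
            if unmapped:
                log.info(
                    "set %r: %d ids had no mapping and were retained verbatim",
                    label, len(unmapped),
                )
        registry.add(NamedSet(label, members))
    return registry


def write_named_sets(registry: SetRegistry, path: str | Path) -> None:
    """Write a registry back in the input dialect (round-trip safe)."""
    with open(path, "w", encoding="utf-8") as fh:
        for named in registry:
            for p in sorted(named.members, key=lambda m: m.id):
                cols = [named.label, p.id]
                if p.symbol:
                    cols.append(p.symbol)
                fh.write("\t".join(cols) + "\n")


def combine_sets(
    registry: SetRegistry, labels: list[str], mode: str = "union"
) -> NamedSet:
    """Set algebra over registry members.

    mode='difference' is left-fold: first label minus all the rest.
    """
    if not labels:
        raise ValueError("combine_sets requires at least one label")
    sets = [registry[lab].members for lab in labels]
    if mode == "union":
        members = set().union(*sets)
        op = "|"
    elif mode == "intersection":
        members = set.intersection(*sets)
        op = "&"
    elif mode == "difference":
        members = sets[0].difference(*sets[1:]) if len(sets) > 1 else set(sets[0])
        op = "-"
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return NamedSet(op.join(labels), members, description=f"{mode} of {labels}")


def summarize_overlaps(
    registry: SetRegistry,
    pairs: list[tuple[str, str]],
    exclude: ProteinRef | None = None,
) -> list[dict]:
    """Pairwise overlap sizes, with and without one excluded protein.

    The exclusion mirrors reporting overlaps "excluding the bait": the bait
    trivially belongs to both its own interactor set and the screen hits.
    """
    rows = []
    for a, b in pairs:
        inter = registry[a].members & registry[b].members
        without = inter - {exclude} if exclude is not None else inter
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "overlap": len(inter),
                "overlap_excluding": len(without),
            }
        )
    return rows
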