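"""Accessors for the packaged reference fixtures.

The package ships three small plain-text references: the 90-row published
candidate feature table (the gold standard for the decision tree and the
ranking), the five-term disease slim, and the printed dataset-size /
overlap expectations.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .prioritize import read_feature_table

#: The six default comparison processes behind the shared-process flag:
#: the five processes enriched in both the screen and the disease-related
#: set by both scores, plus protein folding (significant by the locally
#: adjusted score in the screen).
DEFAULT_COMPARISON_TERMS = (
    "GO:0006986",  # response to unfolded protein
    "GO:0007005",  # mitochondrion organization
    "GO:0046907",  # intracellular transport
    "GO:0051649",  # establishment of localization in cell
    "GO:0043623",  # cellular protein complex assembly
    "GO:0006457",  # protein folding
)


def _data_path(name: str) -> Path:
    return Path(resources.files("tapprio").joinpath("data", name))


def load_reference_features() -> list[dict]:
    """The published 90-row candidate feature table, in printed order."""
    return read_feature_table(_data_path("table2_candidates.tsv"))


def load_disease_slim() -> dict[str, str]:
    """The five-term disease slim as {term_id: name}."""
    slim: dict[str, str] = {}
    with open(_data_path("goslim_pd.tsv"), encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            term, name = line.split("\t")
            slim[term] = name
    return slim


def load_dataset_counts() -> dict:
    """Printed dataset sizes, union structure and pairwise overlaps."""
    with open(_data_path("table1_counts.json"), encoding="utf-8") as fh:
        return json.load(fh)
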