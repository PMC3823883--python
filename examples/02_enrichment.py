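"""Classic vs locally adjusted term enrichment on a tiny planted corpus.

The study set is exactly the proteins annotated to one specific leaf term,
so the leaf is maximally enriched. Its parent covers the same proteins and
is equally significant by the classic hypergeometric score — but the local
(elim-style) score discounts the parent once the leaf has claimed the
signal, which is how generic terms are down-weighted against their more
specific descendants.
"""

import tempfile
import textwrap
from pathlib import Path

from tapprio import classic_enrichment, local_adjusted_enrichment
from tapprio.ontology import load_ontology, propagate

OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root

[Term]
id: GO:0000002
name: generic parent
is_a: GO:0000001

[Term]
id: GO:0000003
name: specific leaf
is_a: GO:0000002
"""

with tempfile.TemporaryDirectory() as tmp:
    obo = Path(tmp) / "toy.obo"
    obo.write_text(textwrap.dedent(OBO))
    dag = load_ontology(obo)

direct = {f"hit{i}": {"GO:0000003"} for i in range(8)}
direct |= {f"bg{i}": {"GO:0000001"} for i in range(32)}
annotations = propagate(dag, direct)

study = {f"hit{i}" for i in range(8)}
classic = {r.term: r.classic_p for r in classic_enrichment(study, dag, annotations)}
local = local_adjusted_enrichment(study, dag, annotations)

for term in ("GO:0000003", "GO:0000002"):
    print(f"{dag.name(term):15s} classic p = {classic[term]:.3g}   "
          f"local p = {local[term]:.3g}")
print("-> the leaf keeps its significance; the parent's local score collapses "
      "to ~1 because its signal is fully explained by the leaf")
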