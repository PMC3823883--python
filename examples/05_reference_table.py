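"""Re-derive the published selection levels from the packaged feature table.

Loads the 90-row reference feature table shipped with the package, pushes
every row through the decision tree, and compares with the printed
selection levels and rank order.
"""

from tapprio import assign_selection_level, rank_table
from tapprio.reference import load_reference_features

rows = load_reference_features()
hits = sum(
    assign_selection_level(r["features"]).level == r["printed_level"] for r in rows
)
ranked = rank_table([r["features"] for r in rows])
order_ok = [f.protein_id for _, f, _ in ranked] == [r["features"].protein_id for r in rows]

print(f"selection levels reproduced: {hits}/{len(rows)}")
print(f"published rank order reproduced: {order_ok}")

for symbol in ("TOMM70A", "HSPD1", "NEFL"):
    row = next(r for r in rows if r["features"].symbol == symbol)
    lvl = assign_selection_level(row["features"])
    print(f"{symbol:8s} -> level {lvl.level} ({lvl.matched_rule})")
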