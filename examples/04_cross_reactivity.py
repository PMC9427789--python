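"""Cross-species epitope conservation and back-mutation design.

Aligns a synthetic binder/non-binder ortholog pair with planted species
differences, maps the differences onto epitope regions, and proposes
"back to binder" mutations singly and in cumulative combinations.
"""

from epidock.crossreact import (
    align_pair,
    difference_positions,
    epitope_overlap,
    propose_back_mutations,
)
from epidock.synthetic import make_ortholog_pair

# non-binder ortholog carries T49/T76/Q117/A159 where the binder species
# has N49/R76/H117/S159
ref, query = make_ortholog_pair(
    170,
    planted_differences={49: "T", 76: "T", 117: "Q", 159: "A"},
    seed=0,
    reference_letters={49: "N", 76: "R", 117: "H", 159: "S"},
)
pair = align_pair(ref, query, reference_id="binder", query_id="non_binder")
print(f"identity over aligned columns: {pair.identity_percent:.1f}%")

epitope = set(range(40, 58)) | set(range(114, 135)) | set(range(144, 162))
diff = difference_positions(pair, epitope_positions=epitope)
count, pct = epitope_overlap(diff, epitope)
print(f"{len(diff.differing)} species differences, {count} on epitope ({pct:.0f}%)")

# propose restoring the binder residues at the four cavity positions
proposal = propose_back_mutations(
    diff, restrict_to={49, 76, 117, 159}, priority_order=[117, 159, 49, 76]
)
print("single back mutations:", ", ".join(proposal.labels))
print("cumulative combination sets:")
for combo in proposal.combination_labels:
    print("  " + " + ".join(combo))
# combinations grow one mutation at a time in the stated priority order,
# mirroring how a rescue experiment would be staged
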