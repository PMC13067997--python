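"""Score classifications with the six-way categorization and rank metrics.

Reads are TP when rank-correct, VP when assigned a strict ancestor of the
truth, FP when assigned a wrong node, FP* when an off-index read is
assigned anything, FN/TN when unclassified.  PPV = TP/(TP+FP+FP*),
sensitivity = TP/(TP+FP+FN+VP).
"""

from colormove import (
    Taxonomy,
    categorize_reads,
    compute_metrics,
)

taxonomy = Taxonomy(
    parents={1: 1, 10: 1, 20: 1, 101: 10, 102: 10, 201: 20},
    ranks={1: "root", 10: "genus", 20: "genus",
           101: "species", 102: "species", 201: "species"},
    names={1: "root", 10: "Escherichia", 20: "Salmonella",
           101: "E. coli", 102: "E. fergusonii", 201: "S. enterica"},
)

truths = {          # read -> true taxon (None = not from the index)
    "r1": 101, "r2": 101, "r3": 101, "r4": 102,
    "r5": 201, "r6": None, "r7": None, "r8": 101,
}
predictions = {     # read -> assigned taxon (absent = unclassified)
    "r1": 101,      # exact species: TP
    "r2": 10,       # genus ancestor of truth: VP at species rank
    "r3": 201,      # wrong species: FP
    "r4": 102,      # TP
    "r5": 201,      # TP
    "r6": 101,      # off-index read assigned: FP*
    # r7 unclassified: TN
    # r8 unclassified: FN
}

for rank in ("species", "genus"):
    counts = categorize_reads(truths, predictions, rank, taxonomy)
    m = compute_metrics(counts)
    print(f"[{rank}] TP={counts.TP} VP={counts.VP} FP={counts.FP} "
          f"FP*={counts.FP_STRICT} FN={counts.FN} TN={counts.TN}  "
          f"PPV={m.ppv:.3f} sens={m.sensitivity:.3f} F1={m.f1:.3f}")
print()
print("At genus rank the VP read becomes a TP (its genus was right), and")
print("the wrong-species FP also lifts to the right genus: metrics improve.")
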