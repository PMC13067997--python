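"""Query a read with pseudo-matching lengths and tally run colors.

The read is processed right to left while one BWT offset is tracked.  Each
position's PML says a match of at least that length starts there; whenever
the PML is positive, the tracked run's color increments every member
document's score.
"""

from colormove import (
    Document,
    ReferenceCollection,
    RepositionStrategy,
    StrandMode,
    build_index,
    compute_pmls_with_colors,
)

collection = ReferenceCollection(
    [Document(0, "D1", ["AAC"]), Document(1, "D2", ["AAG"])],
    StrandMode.FORWARD_ONLY,
)
index = build_index(collection)

read = "AAG"
result, scores = compute_pmls_with_colors(
    read, index, RepositionStrategy.LCP_THRESHOLDS
)
print(f"read:   {read}")
print(f"PMLs:   {result.lengths}")
print("        L[k] > 0 means read[k : k+L[k]] occurs somewhere in the index;")
print("        the rightmost position restarted matching, hence its 0.")
print(f"scores: { {f'D{d + 1}': s for d, s in sorted(scores.items())} }")
print("        both documents score 2: the matches 'AA' and 'A' occur in both,")
print("        so their shared runs tie the documents at the top.")
print(f"average PML: {result.average:.3f}  (the binary-classification statistic)")
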