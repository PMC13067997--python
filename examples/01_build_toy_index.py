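"""Build a colored move-structure index over two tiny documents.

Shows the full anatomy on an index small enough to read: the concatenated
text, suffix array, BWT, its runs, and the color (document set) of every
run.
"""

from colormove import (
    Document,
    ReferenceCollection,
    StrandMode,
    build_index,
    index_stats,
)
from colormove.collection import concatenate_documents

collection = ReferenceCollection(
    [Document(0, "D1", ["AAC"]), Document(1, "D2", ["AAG"])],
    StrandMode.FORWARD_ONLY,
)
text = concatenate_documents(collection)
index = build_index(collection, keep_suffix_structures=True)
s = index.full.structures

print(f"text:          {text.text}")
print(f"suffix array:  {s.suffix_array.tolist()}")
print(f"BWT:           {s.bwt}")
print(f"document/row:  {s.doc_array.tolist()}  (-1 = terminator row)")
print()
print("run  char  rows   color (documents whose suffixes fill the run)")
for i in range(index.move.num_runs):
    start = int(index.move.starts[i])
    length = int(index.move.lengths[i])
    color = sorted(index.colors.color_of_run(i))
    char = "ACGT$"[int(index.move.char_codes[i]) - 1] if index.move.char_codes[i] else "$"
    print(f"{i:3d}  {char:4s}  {start}-{start + length - 1}    {color}")
print()
stats = index_stats(index.move, index.colors)
print(f"n={stats.n}  r={stats.r}  |C|={stats.num_colors}  "
      f"n/r={stats.n_over_r:.2f}  r/|C|={stats.runs_per_color:.2f}")
print("n/r and r/|C| grow with redundancy: repetitive collections have few,")
print("long runs that keep reusing the same document sets.")
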