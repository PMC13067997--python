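# Methods

## Index model

The index is built over the concatenation of all documents in ID order,
followed (by default) by the reverse complement of every sequence under the
same document ID, and a single terminal `$` that sorts before `A < C < G <
T`. A *document* is the unit the classifier can report: one genome, or all
genomes of a species, chosen when the collection is assembled. Reverse
complements share their document's ID so one right-to-left query pass
covers both strands. There are no per-document separators; the rare
suffixes that cross a document boundary are attributed to the document
containing their starting offset, and the terminator's row carries a
no-document sentinel that never contributes to colors.

Construction computes, in order: the suffix array (naive sorting up to
4 kb — also the oracle used in tests — and numpy prefix doubling above
that, O(n log² n)); the BWT by definition; the LCP array with Kasai's
algorithm; the document array by binary search over boundary offsets; the
maximal equal-letter runs; the move table; and the per-run colors. The
naive/doubling switch is purely a speed choice; both paths are checked
against sorted-suffix oracles. Construction targets collections up to a
few megabases on one CPU; larger inputs would need an external-memory BWT
builder, which is out of scope.

### Move table

One row per BWT run stores `(c, l, xi, f)`: run character, length, and the
run/offset coordinates of the LF image of the run head. Because all rows of
a run share a character, their LF images are contiguous, so
`LF(i, j) = (xi_i, f_i + j)` followed by a fast-forward that walks forward
through runs while the offset exceeds the destination run's length. The
fast-forward is iterative; the worst case is not constant time (the
row-splitting normalization that guarantees O(1) is an optimization we do
not need at this scale), but equality with rank-based LF is verified
exhaustively in tests.

### Thresholds and repositioning

When the tracked run's character differs from the read character (case 2),
the query repositions to the nearest row carrying that character: the
*last* row of the nearest matching run above, or the *first* row of the
nearest matching run below — the two candidates that maximize the LCP
retained with the current row. Which direction wins is precomputed per run
and character as a threshold offset `t in [0, l]`: offsets `< t` go up,
offsets `>= t` go down, where the winning direction has the larger
range-minimum LCP between the current row and the candidate. Ties break
upward, consistent with the always-up fallback; `t = l` when no occurrence
exists below, `t = 0` when none above. Two threshold-free strategies are
provided for indexes built without LCP information: `mid-run` (up iff the
offset is below `ceil(l/2)`) and `always-up`, each falling back to the only
available direction.

## Query and classification

PML computation starts at the position of `BWT[n-1]` and scans the read
right to left. Case 1 increments the running length; case 2 repositions and
resets it to zero. After a position's length is fixed and before the LF
step, a positive length looks up the color of the run containing the
tracked offset and increments the score of each member document. Read
characters absent from the index (e.g. `N`) record length zero and leave
the position unchanged. Scores are always computed; the binary gate only
sets the classified/unclassified status.

- **Binary gate**: in-index iff average PML is *strictly above* the cutoff;
  the cutoff is the nearest-rank 95th percentile (configurable `alpha`) of
  null-read average PMLs. The cutoff is calibrated once per index with the
  default (threshold-based) strategy and reused by the alternative
  strategies: it is a property of the index, and recalibrating per strategy
  only injects quantile noise into comparisons.
- **Document report**: the highest-scoring document (ties to the smallest
  ID, for determinism), then up to `max_extra = 1` further documents with
  score `>= 0.95 ×` the best (inclusive), in descending score order.
- **LCA**: the reported documents' taxa are resolved in a parent-pointer
  taxonomy; a single reported document yields its own taxon. A read whose
  score map is empty stays unclassified regardless of the gate.

Reads are processed independently; results do not depend on batch order.

## Color fidelity

For diagnostics the engine can run exact backward search alongside the PML
pass: during a case-1 streak the match grows by one character per step, so
one LF-interval extension per position maintains the suffix-array interval
of the *exact* current match, and the distinct document array entries over
that interval are the true containing documents. Two color-derived sets are
compared against this truth by Jaccard similarity, per PML value:

- the single color of the tracked run (what one tally step sees), and
- the **score-supported set**: documents present in *every* color tallied
  since the match began — precisely the documents whose score has grown at
  every step of the streak, which is the guarantee the scoring argument
  rests on.

The single-run color is noisy at every match length: a BWT run extends past
a species' block of rows whenever the flanking rows happen to share the
preceding character, and one foreign row poisons the whole run's color.
This noise does not diminish with match length, so per-run fidelity
plateaus (around 0.8 on our synthetic pangenomes). The score-supported set
washes those sporadic documents out across the streak; its fidelity rises
with PML and exceeds 0.95 on average for PMLs ≥ 16, approaching 1 for long
matches. Fidelity is therefore reported for the score-supported set, with
the per-run value alongside.

## Synthetic pangenomes

The generator emulates a reference collection with both redundancy and
variability: a random ancestor sequence is mutated into per-species
ancestors at the inter-species substitution rate, and each species ancestor
into its genomes at the intra-species rate. One genome per species is held
out of the index and used to simulate *positive* reads — reads whose
species is indexed but whose exact strain is not. *Null* reads come from an
independently drawn clade sharing no ancestry with the index. Reads carry
configurable substitution/insertion/deletion errors and are drawn from both
strands when the index covers both.

Default conditions (one `SimulationConfig`): 10 species × 5 genomes of
20 kb, intra-species divergence 0.001, inter-species 0.05, 2 kb reads with
5% substitution error (an ONT-like error level; indels default to zero so
error placement stays position-exact). The `document_level` switch selects
genome-level documents (multi-class listing) or species-level documents
(taxonomic classification and the fidelity analysis — grouping a species'
genomes into one document absorbs strain-private variation, which is what
makes long matches document-pure). The test suite uses a smaller instance
of the same design (6 species × 4 genomes of 8 kb, 1 kb reads) so the whole
suite stays fast.

What the generator does *not* emulate: indels and rearrangements between
genomes, gene content differences, horizontal transfer, GC/composition
bias, or a realistic long-read error profile. Substitution-only evolution
on a shared coordinate system makes distinct "species" far more homologous
than real diverse bacteria; conclusions about absolute per-run color purity
transfer to real data only qualitatively. The binary-gate separation it
produces is, if anything, conservative in one respect (a 5% inter-species
rate keeps null-like structure nearby) and optimistic in another (no
contaminant k-mer sharing from real conserved genes).

An empirical note on null reads: their average PML does not track the
matching-statistic scale `log4(n)`. PMLs reset to zero at every case 2 and
a random read re-matches the single tracked row with probability ~1/4 per
step, so null average PMLs concentrate around ~0.3 almost independently of
`n`, while reads genuinely in the index average tens. The gate's power at
desk scale is correspondingly near 1.

## Numerical and design choices

- Coordinates are 0-based half-open throughout; the alphabet is ordered
  `$ < A < C < G < T`.
- References are sanitized by splitting at non-ACGT characters rather than
  substituting bases; query characters outside the alphabet always behave
  as case 2 with no movement.
- Threshold ties break upward; best-document ties break to the smallest ID;
  the runner-up rule is inclusive (`>=`).
- Empty colors (runs holding only the terminator row) are legal and score
  nothing.
- Color IDs are assigned in first-occurrence order, making serialization
  byte-stable; the index directory round-trips losslessly and re-saving is
  byte-identical.
- Degenerate inputs: empty collections, sequences empty after sanitization,
  empty reads, empty null samples, and `alpha` outside (0, 1) raise; a
  single-`$` text yields an all-sentinel document array.
- All randomness flows from one integer seed through named
  `numpy.random.default_rng([seed, stream])` streams, so every artifact is
  reproducible byte-for-byte.

## Limitations

- The classifier cannot report below the document granularity chosen at
  build time (species documents ⇒ no strain-level calls).
- Suffix-array construction is in-memory; multi-gigabase references are out
  of scope.
- The move table is not row-split, so worst-case LF cost is O(runs
  traversed), not O(1); irrelevant at desk scale.
- Color storage is a plain deduplicated table; meta-color or spanning-tree
  compression schemes are not implemented.
- Abundance estimation from per-document scores is not implemented.
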