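"""Pseudo-matching lengths with color tallying, and read classification.

The PML pass walks a read right to left while tracking a single BWT offset.
At each position the tracked row's character either matches the read (case
1: length grows by one) or not (case 2: reposition to the nearest matching
row and reset the length to zero).  Whenever the recorded length is
positive, the color of the run containing the tracked row is looked up and
every member document's score is incremented.  The resulting per-document
scores drive multi-class classification; their maximum-scoring documents
(best plus runners-up within a configurable ratio) are reported and the
read is assigned the LCA of their taxa.  A binary average-PML gate,
calibrated on null reads, filters out reads that do not belong to the index
at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import CHAR_TO_CODE
from .collection import NO_DOCUMENT
from .index import ColorMoveIndex
from .move import RepositionStrategy

UNCLASSIFIED = "U"
CLASSIFIED = "C"


@dataclass
class PMLResult:
    """Per-position pseudo-matching lengths and the color IDs tallied."""

    lengths: list[int]
    color_ids: list[int | None]

    @property
    def average(self) -> float:
        return average_pml(self.lengths, len(self.lengths))


@dataclass(frozen=True)
class FidelityRecord:
    """One position of the color-fidelity analysis.

    ``color`` is the current run's document set; ``supported`` the documents
    present in every color tallied during the current case-1 streak (the
    documents whose score grew at every step); ``truth`` every document
    containing the exact match.
    """

    length: int
    color: frozenset
    supported: frozenset
    truth: frozenset


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def color_fidelity(
    engine: "QueryEngine", reads: list[str], min_length: int = 16
) -> dict:
    """Mean Jaccard between score-supported and true document sets.

    Aggregates :meth:`QueryEngine.fidelity_trace` over reads, per PML value
    and overall, for both the raw per-run color and the score-supported set.
    """
    by_length: dict[int, list[float]] = {}
    supported_j: list[float] = []
    color_j: list[float] = []
    for read in reads:
        for rec in engine.fidelity_trace(read, min_length=min_length):
            j = jaccard(rec.supported, rec.truth)
            supported_j.append(j)
            color_j.append(jaccard(rec.color, rec.truth))
            by_length.setdefault(rec.length, []).append(j)
    mean = lambda v: sum(v) / len(v) if v else float("nan")
    return {
        "mean_supported": mean(supported_j),
        "mean_color": mean(color_j),
        "by_length": {L: mean(v) for L, v in sorted(by_length.items())},
        "positions": len(supported_j),
    }


@dataclass
class ClassificationRecord:
    read_id: str
    status: str  # CLASSIFIED or UNCLASSIFIED
    average_pml: float
    documents: list[int] = field(default_factory=list)
    taxon_id: int | None = None
    taxon_rank: str = ""
    scores: dict[int, int] = field(default_factory=dict)


class QueryEngine:
    """Reusable PML/color query state for one index and strategy.

    Columns of the move and color tables are materialized as Python lists:
    the PML loop is a tight scalar loop and list indexing is several times
    faster than numpy scalar access.
    """

    def __init__(
        self,
        index: ColorMoveIndex,
        strategy: RepositionStrategy = RepositionStrategy.LCP_THRESHOLDS,
    ):
        move = index.move
        self.index = index
        self.strategy = RepositionStrategy(strategy)
        if (
            self.strategy is RepositionStrategy.LCP_THRESHOLDS
            and move.thresholds is None
        ):
            raise ValueError(
                "index built without thresholds; use mid-run or always-up"
            )
        self.run_char = move.char_codes.tolist()
        self.run_len = move.lengths.tolist()
        self.dest_run = move.dest_run.tolist()
        self.dest_off = move.dest_offset.tolist()
        self.above = move.above.tolist()
        self.below = move.below.tolist()
        self.thresholds = (
            move.thresholds.tolist() if move.thresholds is not None else None
        )
        self.color_id = (
            move.color_ids.tolist()
            if move.color_ids is not None
            else [0] * move.num_runs
        )
        self.color_docs = [tuple(sorted(c)) for c in index.colors.colors]
        self.present = set(self.run_char)
        self.num_runs = move.num_runs
        self.n = move.n

    def _start(self) -> tuple[int, int]:
        """Tracked offset starts at BWT[n-1], the last row."""
        last = self.num_runs - 1
        return last, self.run_len[last] - 1

    def pml(self, read: str) -> tuple[PMLResult, dict[int, int]]:
        """PMLs plus tallied per-document scores for one read."""
        if not read:
            raise ValueError("empty read")
        m = len(read)
        lengths = [0] * m
        color_ids: list[int | None] = [None] * m
        scores: dict[int, int] = {}
        run, off = self._start()
        mid = self.strategy is RepositionStrategy.MID_RUN
        always_up = self.strategy is RepositionStrategy.ALWAYS_UP
        run_char, run_len = self.run_char, self.run_len
        dest_run, dest_off = self.dest_run, self.dest_off
        above, below = self.above, self.below
        thresholds = self.thresholds
        color_id, color_docs = self.color_id, self.color_docs
        length = 0
        for k in range(m - 1, -1, -1):
            c = CHAR_TO_CODE.get(read[k], -1)
            if c < 0 or c not in self.present:
                # character absent from the index: PML 0, no movement
                length = 0
                continue
            if run_char[run] == c:
                length += 1  # case 1
            else:
                # case 2: reposition, reset
                up, down = above[run][c], below[run][c]
                if up < 0:
                    go_up = False
                elif down < 0:
                    go_up = True
                elif always_up:
                    go_up = True
                elif mid:
                    go_up = off < (run_len[run] + 1) // 2
                else:
                    go_up = off < thresholds[run][c]
                if go_up:
                    run = up
                    off = run_len[up] - 1
                else:
                    run = down
                    off = 0
                length = 0
            lengths[k] = length
            if length > 0:
                cid = color_id[run]
                color_ids[k] = cid
                for d in color_docs[cid]:
                    scores[d] = scores.get(d, 0) + 1
            # LF step with fast-forward
            off += dest_off[run]
            run = dest_run[run]
            while off >= run_len[run]:
                off -= run_len[run]
                run += 1
        return PMLResult(lengths, color_ids), scores

    def fidelity_trace(
        self, read: str, min_length: int = 1
    ) -> list["FidelityRecord"]:
        """Per-position comparison of color-derived and true document sets.

        For every position whose PML is at least ``min_length`` this records
        the current run's color, the *score-supported* document set (the
        documents present in every color tallied since the current match
        began — exactly the documents whose score has grown at every step of
        the case-1 streak), and the true set of documents containing the
        exact match ``R[k..k+L-1]``.  The truth is obtained by running
        backward search alongside the PML pass and listing the distinct
        documents over the resulting suffix-array interval.  Requires an
        index built with ``keep_suffix_structures=True``.
        """
        full = self.index.full
        if full is None:
            raise ValueError("index was built without suffix structures")
        occ = full.occ
        doc_array = full.structures.doc_array
        cbase = occ[-1].cumsum() - occ[-1]  # C[] array from total counts
        n = self.n
        m = len(read)
        run, off = self._start()
        mid = self.strategy is RepositionStrategy.MID_RUN
        always_up = self.strategy is RepositionStrategy.ALWAYS_UP
        run_char, run_len = self.run_char, self.run_len
        above, below = self.above, self.below
        thresholds = self.thresholds
        color_sets = [frozenset(c) for c in self.color_docs]
        out: list[FidelityRecord] = []
        length = 0
        lo, hi = 0, n
        supported: frozenset | None = None
        for k in range(m - 1, -1, -1):
            c = CHAR_TO_CODE.get(read[k], -1)
            if c < 0 or c not in self.present:
                length = 0
                lo, hi = 0, n
                supported = None
                continue
            if run_char[run] == c:
                length += 1
                # extend the backward-search interval: it now covers exactly
                # the rows whose suffixes start with the match R[k..k+length-1]
                lo = int(cbase[c] + occ[lo, c])
                hi = int(cbase[c] + occ[hi, c])
            else:
                up, down = above[run][c], below[run][c]
                if up < 0:
                    go_up = False
                elif down < 0:
                    go_up = True
                elif always_up:
                    go_up = True
                elif mid:
                    go_up = off < (run_len[run] + 1) // 2
                else:
                    go_up = off < thresholds[run][c]
                if go_up:
                    run, off = up, run_len[up] - 1
                else:
                    run, off = down, 0
                length = 0
                lo, hi = 0, n
                supported = None
            if length > 0:
                color = color_sets[self.color_id[run]]
                supported = color if supported is None else (supported & color)
                if length >= min_length:
                    block = doc_array[lo:hi]
                    truth = frozenset(
                        int(d) for d in np.unique(block) if d != NO_DOCUMENT
                    )
                    out.append(
                        FidelityRecord(length, color, supported or color, truth)
                    )
            off += self.dest_off[run]
            run = self.dest_run[run]
            while off >= run_len[run]:
                off -= run_len[run]
                run += 1
        return out


def compute_pmls_with_colors(
    read: str,
    index: ColorMoveIndex,
    strategy: RepositionStrategy = RepositionStrategy.LCP_THRESHOLDS,
) -> tuple[PMLResult, dict[int, int]]:
    """One-shot PML + color tally (builds a throwaway engine)."""
    return QueryEngine(index, strategy).pml(read)


def average_pml(lengths, m: int) -> float:
    """Sum of all PMLs divided by the read length."""
    if m <= 0:
        raise ValueError("read length must be positive")
    return float(sum(lengths)) / m


def calibrate_cutoff(null_averages, alpha: float = 0.05) -> float:
    """Nearest-rank (1 - alpha) percentile of null-read average PMLs.

    With alpha = 0.05 this is a level-0.05 significance cutoff: at most 5%
    of the calibration sample exceeds it.
    """
    values = sorted(float(v) for v in null_averages)
    if not values:
        raise ValueError("empty null sample")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    rank = math.ceil((1.0 - alpha) * len(values))  # 1-indexed nearest rank
    return values[max(rank, 1) - 1]


def binary_classify(avg: float, cutoff: float) -> bool:
    """True (in-index) iff the average PML is strictly above the cutoff."""
    return avg > cutoff


def report_documents(
    scores: dict[int, int], ratio: float = 0.95, max_extra: int = 1
) -> list[int]:
    """Best-scoring document plus runners-up within ``ratio`` of the best.

    Ties for the best break toward the smallest document ID; runners-up are
    ordered by descending score (then ascending ID) and capped at
    ``max_extra``.  An all-zero or empty score map yields an empty report.
    """
    if not scores:
        return []
    best_score = max(scores.values())
    if best_score <= 0:
        return []
    best_doc = min(d for d, s in scores.items() if s == best_score)
    extras = sorted(
        (
            (d, s)
            for d, s in scores.items()
            if d != best_doc and s >= ratio * best_score
        ),
        key=lambda ds: (-ds[1], ds[0]),
    )
    return [best_doc] + [d for d, _ in extras[:max_extra]]


def assign_taxon(doc_ids: list[int], doc_taxa: list[int], taxonomy) -> int:
    """LCA of the reported documents' taxa (a single document maps to its own)."""
    if not doc_ids:
        raise ValueError("no documents to assign")
    taxa = []
    for d in doc_ids:
        t = doc_taxa[d]
        if t < 0 or t not in taxonomy:
            raise KeyError(f"document {d} has no taxon mapping")
        taxa.append(t)
    return taxonomy.lca(taxa)


def classify_read(
    read_id: str,
    read: str,
    engine: QueryEngine,
    cutoff: float | None = None,
    ratio: float = 0.95,
    max_extra: int = 1,
) -> ClassificationRecord:
    """Full pipeline for one read: PML+scores, binary gate, report, LCA."""
    pml, scores = engine.pml(read)
    avg = pml.average
    passed = cutoff is None or binary_classify(avg, cutoff)
    docs = report_documents(scores, ratio=ratio, max_extra=max_extra) if passed else []
    if not docs:
        return ClassificationRecord(read_id, UNCLASSIFIED, avg, scores=scores)
    index = engine.index
    taxon: int | None = None
    rank = ""
    if index.taxonomy is not None:
        taxon = assign_taxon(docs, index.doc_taxa, index.taxonomy)
        rank = index.taxonomy.rank_of(taxon)
    return ClassificationRecord(
        read_id, CLASSIFIED, avg, docs, taxon, rank, scores
    )


def classify_reads(
    reads: list[tuple[str, str]],
    index: ColorMoveIndex,
    strategy: RepositionStrategy = RepositionStrategy.LCP_THRESHOLDS,
    cutoff: float | None = None,
    ratio: float = 0.95,
    max_extra: int = 1,
) -> list[ClassificationRecord]:
    """Classify (read_id, sequence) pairs independently and in order."""
    engine = QueryEngine(index, strategy)
    return [
        classify_read(rid, seq, engine, cutoff=cutoff, ratio=ratio, max_extra=max_extra)
        for rid, seq in reads
    ]
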