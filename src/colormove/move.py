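"""The move table: run-level LF mapping with fast-forwarding and repositioning.

Each BWT run becomes one table row holding its character, length, and the
run/offset pair ``(xi, f)`` locating the LF image of the run head.  An LF
step from ``(run i, offset j)`` lands at ``(xi_i, f_i + j)`` followed by a
fast-forward that walks into subsequent runs while the offset spills past a
run's length.  Because all rows of a run share one character, their LF
images are contiguous, so this reproduces the rank-based LF mapping exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .alphabet import CHAR_TO_CODE, SIGMA
from .suffix import (
    THRESHOLD_ABSENT,
    RunBoundary,
    compute_thresholds,
    nearest_run_tables,
    run_arrays,
)


class RepositionStrategy(str, Enum):
    """How case-2 repositioning picks the up/down direction."""

    LCP_THRESHOLDS = "thresholds"
    MID_RUN = "mid-run"
    ALWAYS_UP = "always-up"


class CharAbsentError(KeyError):
    """The query character never occurs in the indexed text."""


@dataclass(frozen=True)
class MovePosition:
    """A BWT offset as (run index, offset within the run)."""

    run: int
    offset: int


@dataclass
class MoveTable:
    """Column-oriented move structure over the BWT runs.

    Arrays are aligned by run index: ``char_codes`` (int8), ``lengths``,
    ``starts`` (global row of each run head), ``dest_run``/``dest_offset``
    (LF image of the head), per-character ``above``/``below`` nearest-run
    tables for repositioning, optional LCP ``thresholds``, and ``color_ids``
    filled in by the color layer.
    """

    char_codes: np.ndarray
    lengths: np.ndarray
    starts: np.ndarray
    dest_run: np.ndarray
    dest_offset: np.ndarray
    above: np.ndarray
    below: np.ndarray
    thresholds: np.ndarray | None = None
    color_ids: np.ndarray | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if self.n == 0:
            self.n = int(self.lengths.sum())

    @property
    def num_runs(self) -> int:
        return len(self.lengths)

    def char_of(self, position: MovePosition) -> str:
        from .alphabet import ALPHABET

        return ALPHABET[int(self.char_codes[position.run])]

    def char_present(self, code: int) -> bool:
        return bool((self.char_codes == code).any())

    def global_row(self, position: MovePosition) -> int:
        return int(self.starts[position.run]) + position.offset

    def position_of_row(self, row: int) -> MovePosition:
        run = int(np.searchsorted(self.starts, row, side="right")) - 1
        return MovePosition(run, row - int(self.starts[run]))


def build_move_table(
    runs: list[RunBoundary],
    bwt: str,
    lcp: np.ndarray | None = None,
    with_thresholds: bool = True,
) -> MoveTable:
    """Build the move table from the run-length encoded BWT.

    The LF image of each run head is computed from cumulative character
    counts: LF(row) = (number of characters smaller than c in the text) +
    (rank of this occurrence of c), evaluated run-wise so no full-text rank
    structure is needed.
    """
    starts, lengths, chars = run_arrays(runs)
    if int(lengths.sum()) != len(bwt):
        raise ValueError("runs do not cover the BWT")
    n = len(bwt)
    counts = np.zeros(SIGMA, dtype=np.int64)
    for c in range(SIGMA):
        counts[c] = int(lengths[chars == c].sum())
    cbase = np.concatenate(([0], np.cumsum(counts)[:-1]))  # C[] array
    # rank of each run head among its character's occurrences
    head_rank = np.zeros(len(runs), dtype=np.int64)
    seen = np.zeros(SIGMA, dtype=np.int64)
    chars_l = chars.tolist()
    lengths_l = lengths.tolist()
    for i in range(len(runs)):
        c = chars_l[i]
        head_rank[i] = seen[c]
        seen[c] += lengths_l[i]
    lf_head = cbase[chars.astype(np.int64)] + head_rank
    dest_run = np.searchsorted(starts, lf_head, side="right") - 1
    dest_offset = lf_head - starts[dest_run]
    above, below = nearest_run_tables(chars)
    thresholds = None
    if with_thresholds:
        if lcp is None:
            raise ValueError("LCP array required for threshold construction")
        thresholds = compute_thresholds(runs, lcp, above, below)
    return MoveTable(
        char_codes=chars,
        lengths=lengths,
        starts=starts,
        dest_run=dest_run.astype(np.int64),
        dest_offset=dest_offset.astype(np.int64),
        above=above,
        below=below,
        thresholds=thresholds,
        n=n,
    )


def lf_step(position: MovePosition, table: MoveTable) -> MovePosition:
    """One LF step with iterative fast-forwarding."""
    run, offset = position.run, position.offset
    if not 0 <= offset < table.lengths[run]:
        raise ValueError(f"invalid position {position}")
    dest = int(table.dest_run[run])
    f = int(table.dest_offset[run]) + offset
    lengths = table.lengths
    while f >= lengths[dest]:
        f -= int(lengths[dest])
        dest += 1
    return MovePosition(dest, f)


def reposition(
    position: MovePosition,
    read_char: str,
    table: MoveTable,
    strategy: RepositionStrategy = RepositionStrategy.LCP_THRESHOLDS,
) -> MovePosition:
    """Move to the nearest row carrying ``read_char`` above or below.

    Up-repositioning lands on the *last* row of the nearest run of
    ``read_char`` above; down-repositioning on the *first* row of the
    nearest run below (both maximize the LCP preserved with the current
    row).  The strategy picks the direction; a direction without any
    candidate falls back to the other one.
    """
    c = CHAR_TO_CODE.get(read_char.upper(), -1)
    if c < 0 or not table.char_present(c):
        raise CharAbsentError(read_char)
    run, offset = position.run, position.offset
    if int(table.char_codes[run]) == c:
        raise ValueError("reposition called on a matching run")
    up_run = int(table.above[run, c])
    down_run = int(table.below[run, c])
    if up_run < 0 and down_run < 0:
        raise CharAbsentError(read_char)
    if up_run < 0:
        go_up = False
    elif down_run < 0:
        go_up = True
    elif strategy is RepositionStrategy.ALWAYS_UP:
        go_up = True
    elif strategy is RepositionStrategy.MID_RUN:
        length = int(table.lengths[run])
        go_up = offset < (length + 1) // 2  # midway: ceil(l/2)
    else:
        if table.thresholds is None:
            raise ValueError("index built without thresholds")
        t = int(table.thresholds[run, c])
        if t == THRESHOLD_ABSENT:
            raise CharAbsentError(read_char)
        go_up = offset < t
    if go_up:
        return MovePosition(up_run, int(table.lengths[up_run]) - 1)
    return MovePosition(down_run, 0)
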