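"""Suffix array, BWT, LCP array, document array, BWT runs and thresholds.

Construction targets correctness at desk scale: the suffix array is built
either by naively sorting suffixes (small inputs, also the test oracle) or
by numpy prefix doubling (Manber-Myers), which handles multi-megabase
concatenations in seconds.  The LCP array uses Kasai's algorithm.

Thresholds are the per-run, per-character offsets that steer case-2
repositioning during pseudo-matching-length queries: within a run of
character ``a``, a query character ``c != a`` can be re-acquired either at
the nearest ``c`` row above or below, and the threshold marks the offset at
which the direction with the larger LCP (between the current row's suffix
and the candidate row's suffix) flips from up to down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import CHAR_TO_CODE, SIGMA, TERMINATOR, encode
from .collection import NO_DOCUMENT, ConcatenatedText

# threshold sentinel: the character never occurs in the BWT
THRESHOLD_ABSENT = -1


def build_suffix_array(text: ConcatenatedText | str) -> np.ndarray:
    """Suffix array of a ``$``-terminated text.

    Dispatches to naive sorting below ~4 kb and prefix doubling above.
    """
    s = text.text if isinstance(text, ConcatenatedText) else text
    if s.count(TERMINATOR) != 1 or not s.endswith(TERMINATOR):
        raise ValueError("text must end with a single terminator '$'")
    if len(s) <= 4096:
        return suffix_array_naive(s)
    codes = text.codes if isinstance(text, ConcatenatedText) else encode(s)
    return _suffix_array_doubling(codes.astype(np.int64))


def suffix_array_naive(s: str) -> np.ndarray:
    """Sort all suffixes directly; quadratic worst case, used as an oracle."""
    return np.array(sorted(range(len(s)), key=lambda i: s[i:]), dtype=np.int64)


def _suffix_array_doubling(codes: np.ndarray) -> np.ndarray:
    """Manber-Myers prefix doubling with numpy lexsort; O(n log^2 n)."""
    n = len(codes)
    rank = codes.copy()
    tmp = np.empty(n, dtype=np.int64)
    k = 1
    while True:
        # rank of suffix i+k, with suffixes shorter than k ranking lowest
        rank_shift = np.full(n, -1, dtype=np.int64)
        rank_shift[: n - k] = rank[k:]
        order = np.lexsort((rank_shift, rank))
        # new ranks: same (rank, rank_shift) pair -> same rank
        pair_neq = (rank[order[1:]] != rank[order[:-1]]) | (
            rank_shift[order[1:]] != rank_shift[order[:-1]]
        )
        tmp[order[0]] = 0
        tmp[order[1:]] = np.cumsum(pair_neq)
        rank, tmp = tmp.copy(), rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


def build_bwt(text: ConcatenatedText | str, suffix_array: np.ndarray) -> str:
    """Last BWM column: the character preceding each sorted suffix."""
    s = text.text if isinstance(text, ConcatenatedText) else text
    n = len(s)
    if len(suffix_array) != n:
        raise ValueError("suffix array length mismatch")
    raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    return raw[(np.asarray(suffix_array) - 1) % n].tobytes().decode("ascii")


def build_lcp(text: ConcatenatedText | str, suffix_array: np.ndarray) -> np.ndarray:
    """Kasai's algorithm: ``lcp[i]`` = LCP of sorted suffixes ``i-1`` and ``i``."""
    s = text.text if isinstance(text, ConcatenatedText) else text
    n = len(s)
    sa = np.asarray(suffix_array)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    rank_l = rank.tolist()
    sa_l = sa.tolist()
    for i in range(n):
        r = rank_l[i]
        if r > 0:
            j = sa_l[r - 1]
            while i + h < n and j + h < n and s[i + h] == s[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def build_document_array(
    suffix_array: np.ndarray, text: ConcatenatedText
) -> np.ndarray:
    """Per-BWM-row document ID; NO_DOCUMENT for the terminator suffix row."""
    sa = np.asarray(suffix_array)
    n = len(sa)
    if not text.boundaries:
        if n > 1:
            raise ValueError("no document boundaries for a non-trivial text")
        return np.full(n, NO_DOCUMENT, dtype=np.int64)
    starts = text.boundary_starts
    ends = np.array([b[1] for b in text.boundaries], dtype=np.int64)
    docs = text.boundary_docs
    idx = np.searchsorted(starts, sa, side="right") - 1
    out = np.where(idx >= 0, docs[np.clip(idx, 0, None)], NO_DOCUMENT)
    inside = (idx >= 0) & (sa < ends[np.clip(idx, 0, None)])
    out = np.where(inside, out, NO_DOCUMENT)
    bad = (out == NO_DOCUMENT) & (sa != n - 1)
    if bad.any():
        raise ValueError(f"offset {int(sa[np.argmax(bad)])} outside all boundaries")
    return out.astype(np.int64)


@dataclass(frozen=True)
class RunBoundary:
    """One maximal equal-letter BWT run."""

    index: int
    start: int
    length: int
    char: str


def run_length_encode(bwt: str) -> list[RunBoundary]:
    """Maximal equal-letter runs of the BWT, in row order."""
    if not bwt:
        raise ValueError("empty BWT")
    raw = np.frombuffer(bwt.encode("ascii"), dtype=np.uint8)
    starts = np.flatnonzero(np.r_[True, raw[1:] != raw[:-1]])
    lengths = np.diff(np.r_[starts, len(raw)])
    return [
        RunBoundary(i, int(s), int(l), bwt[int(s)])
        for i, (s, l) in enumerate(zip(starts, lengths))
    ]


def run_arrays(runs: list[RunBoundary]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(starts, lengths, char codes) columns for a run list."""
    starts = np.array([r.start for r in runs], dtype=np.int64)
    lengths = np.array([r.length for r in runs], dtype=np.int64)
    chars = np.array([CHAR_TO_CODE[r.char] for r in runs], dtype=np.int8)
    return starts, lengths, chars


class RangeMinSparseTable:
    """O(1) range-minimum queries over an integer array after O(n log n) setup."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=np.int32)
        n = len(values)
        levels = max(1, n.bit_length())
        self._table = [values]
        for j in range(1, levels):
            half = 1 << (j - 1)
            prev = self._table[-1]
            if len(prev) <= half:
                break
            self._table.append(np.minimum(prev[:-half], prev[half:]))

    def query(self, lo, hi):
        """Minimum over the inclusive range [lo, hi]; vectorized over arrays."""
        scalar = np.isscalar(lo) or np.ndim(lo) == 0
        lo = np.atleast_1d(np.asarray(lo, dtype=np.int64))
        hi = np.atleast_1d(np.asarray(hi, dtype=np.int64))
        span = hi - lo + 1
        if (span <= 0).any():
            raise ValueError("empty range-minimum query")
        j = np.frexp(span.astype(np.float64))[1] - 1  # floor(log2(span))
        result = np.empty(len(lo), dtype=np.int32)
        for level in np.unique(j):
            mask = j == level
            t = self._table[int(level)]
            a = lo[mask]
            b = hi[mask] - (1 << int(level)) + 1
            result[mask] = np.minimum(t[a], t[b])
        return int(result[0]) if scalar else result


def nearest_run_tables(
    run_chars: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """For every run and character code, the nearest run above/below with
    that character (-1 when none exists).  Shapes ``(r, SIGMA)``."""
    r = len(run_chars)
    above = np.full((r, SIGMA), -1, dtype=np.int64)
    below = np.full((r, SIGMA), -1, dtype=np.int64)
    for c in range(SIGMA):
        where = np.flatnonzero(run_chars == c)
        if len(where) == 0:
            continue
        pos = np.searchsorted(where, np.arange(r))
        # nearest strictly above: last element of `where` before run i
        ab = np.where(pos > 0, where[np.clip(pos - 1, 0, None)], -1)
        # nearest strictly below: first element of `where` at/after i, skip self
        pos_below = np.searchsorted(where, np.arange(r), side="right")
        be = np.where(pos_below < len(where), where[np.clip(pos_below, None, len(where) - 1)], -1)
        above[:, c] = ab
        below[:, c] = be
        above[where, c] = np.where(pos[where] > 0, where[np.clip(pos[where] - 1, 0, None)], -1)
    return above, below


def compute_thresholds(
    runs: list[RunBoundary],
    lcp: np.ndarray,
    above: np.ndarray | None = None,
    below: np.ndarray | None = None,
) -> np.ndarray:
    """Per-run, per-character repositioning thresholds.

    Returns an ``(r, SIGMA)`` int64 array ``t`` with the contract: within run
    ``i``, offsets ``j < t[i, c]`` reposition up (to the nearest row of
    character ``c`` above) and offsets ``j >= t[i, c]`` reposition down.  The
    winning direction is the one whose candidate row shares the longer LCP
    with the current row (range-minimum over the LCP array); ties break
    upward.  ``t = length`` when no occurrence of ``c`` exists below,
    ``t = 0`` when none above, and :data:`THRESHOLD_ABSENT` when the
    character never occurs in the BWT.
    """
    starts, lengths, run_chars = run_arrays(runs)
    r = len(runs)
    if above is None or below is None:
        above, below = nearest_run_tables(run_chars)
    rmq = RangeMinSparseTable(lcp)
    thresholds = np.full((r, SIGMA), THRESHOLD_ABSENT, dtype=np.int64)
    ends = starts + lengths  # exclusive
    INF = 1 << 60
    # constant LCP parts from the nearest candidate row to the run boundary,
    # per character; sentinel where a direction has no candidate
    b_up = np.full((r, SIGMA), -1, dtype=np.int64)
    b_down = np.full((r, SIGMA), -1, dtype=np.int64)
    for c in range(1, SIGMA):  # reads never query '$'
        has_above = np.flatnonzero(above[:, c] >= 0)
        has_below = np.flatnonzero(below[:, c] >= 0)
        if len(has_above):
            up_rows = starts[above[has_above, c]] + lengths[above[has_above, c]] - 1
            b_up[has_above, c] = rmq.query(up_rows + 1, starts[has_above])
        if len(has_below):
            down_rows = starts[below[has_below, c]]
            b_down[has_below, c] = rmq.query(ends[has_below], down_rows)
        thresholds[above[:, c] >= 0, c] = lengths[above[:, c] >= 0]  # only-up default
        thresholds[(above[:, c] < 0) & (below[:, c] >= 0), c] = 0
    lcp_l = np.asarray(lcp, dtype=np.int64).tolist()
    starts_l, lengths_l = starts.tolist(), lengths.tolist()
    chars_l = run_chars.tolist()
    bu_l, bd_l = b_up.tolist(), b_down.tolist()
    for i in range(r):
        s, length, own = starts_l[i], lengths_l[i], chars_l[i]
        inner = lcp_l[s + 1 : s + length]
        # prefix mins (up_lcp without the constant part) and suffix mins (down)
        pref = [INF]
        m = INF
        for v in inner:
            m = v if v < m else m
            pref.append(m)
        suf = [INF] * length
        m = INF
        for j in range(length - 2, -1, -1):
            v = inner[j]
            m = v if v < m else m
            suf[j] = m
        row_bu, row_bd = bu_l[i], bd_l[i]
        for c in range(1, SIGMA):
            if c == own:
                thresholds[i, c] = length  # case 1 never repositions
                continue
            bu, bd = row_bu[c], row_bd[c]
            if bu < 0 or bd < 0:
                continue  # single-direction / absent cases already set
            t = 0
            for j in range(length):
                up = bu if bu < pref[j] else pref[j]
                down = bd if bd < suf[j] else suf[j]
                if up >= down:  # ties break upward
                    t = j + 1
                else:
                    break
            thresholds[i, c] = t
    return thresholds


def build_suffix_structures(text: ConcatenatedText):
    """Convenience: SA, BWT, LCP and document array in one call."""
    sa = build_suffix_array(text)
    bwt = build_bwt(text, sa)
    lcp = build_lcp(text, sa)
    doc = build_document_array(sa, text)
    return sa, bwt, lcp, doc
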