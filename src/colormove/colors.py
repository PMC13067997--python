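"""Run colors: per-run document sets, deduplicated into a color table.

A run's *color* is the set of documents whose suffixes populate its BWM
rows.  On repetitive inputs many runs share a color, so each distinct color
gets an ID (first-occurrence order) and only the ID is stored per run.  The
ratio of runs to distinct colors, r/|C|, measures how much this sharing
saves over storing one document set per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .collection import NO_DOCUMENT
from .suffix import RunBoundary

Color = frozenset  # of document IDs


class ColorEncoding(str, Enum):
    DENSE = "dense"
    SPARSE = "sparse"


def compute_run_colors(runs: list[RunBoundary], doc_array: np.ndarray) -> list[Color]:
    """Distinct document IDs per run, excluding the terminator sentinel."""
    doc = np.asarray(doc_array)
    out: list[Color] = []
    for r in runs:
        block = doc[r.start : r.start + r.length]
        distinct = np.unique(block)
        out.append(frozenset(int(d) for d in distinct if d != NO_DOCUMENT))
    return out


@dataclass
class ColorTable:
    """Deduplicated colors and the per-run color-ID array."""

    colors: list[Color]
    per_run_ids: np.ndarray
    num_documents: int
    encoding: ColorEncoding = ColorEncoding.SPARSE

    @property
    def num_colors(self) -> int:
        return len(self.colors)

    def color_of_run(self, run: int) -> Color:
        return self.colors[int(self.per_run_ids[run])]

    # -- occupancy statistics ------------------------------------------------

    @property
    def mean_set_bits(self) -> float:
        """b: average number of documents per distinct color."""
        if not self.colors:
            return 0.0
        return sum(len(c) for c in self.colors) / len(self.colors)

    def dense_size_bits(self) -> int:
        """Size of the |C| x |D| presence-bitvector representation."""
        return self.num_colors * self.num_documents

    def sparse_size_integers(self) -> int:
        """Total set-bit offsets stored across colors (|C| x b integers)."""
        return sum(len(c) for c in self.colors)

    def color_frequencies(self) -> np.ndarray:
        """Runs per color ID, aligned with ``colors``."""
        return np.bincount(self.per_run_ids, minlength=self.num_colors)


def deduplicate_colors(
    per_run_colors: list[Color],
    num_documents: int,
    encoding: ColorEncoding = ColorEncoding.SPARSE,
) -> ColorTable:
    """Assign stable color IDs in first-occurrence order."""
    ids: dict[Color, int] = {}
    per_run = np.empty(len(per_run_colors), dtype=np.int64)
    colors: list[Color] = []
    for i, color in enumerate(per_run_colors):
        cid = ids.get(color)
        if cid is None:
            cid = len(colors)
            ids[color] = cid
            colors.append(color)
        per_run[i] = cid
    return ColorTable(colors, per_run, num_documents, encoding)


def encode_color(
    color: Color, mode: ColorEncoding, num_documents: int
) -> tuple[np.ndarray, int]:
    """Encode one color; returns (encoded array, size in bits).

    Dense: a |D|-entry presence bitvector (size |D| bits).  Sparse: sorted
    set-bit offsets (size counted as one machine integer per document,
    reported in bits assuming 32-bit integers).
    """
    if any(d < 0 or d >= num_documents for d in color):
        raise ValueError("document ID outside the document universe")
    if mode is ColorEncoding.DENSE:
        bits = np.zeros(num_documents, dtype=np.uint8)
        bits[sorted(color)] = 1
        return bits, num_documents
    offsets = np.array(sorted(color), dtype=np.int64)
    return offsets, 32 * len(offsets)


def decode_color(encoded: np.ndarray, mode: ColorEncoding) -> Color:
    if mode is ColorEncoding.DENSE:
        return frozenset(int(i) for i in np.flatnonzero(encoded))
    return frozenset(int(i) for i in encoded)


@dataclass
class IndexStats:
    n: int
    r: int
    num_colors: int
    runs_per_color: float  # r/|C|
    n_over_r: float
    mean_set_bits: float
    dense_size_bits: int
    sparse_size_integers: int
    # descending run counts per color with cumulative run coverage
    color_frequency: np.ndarray = field(repr=False, default=None)
    cumulative_coverage: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "r": self.r,
            "|C|": self.num_colors,
            "r/|C|": self.runs_per_color,
            "n/r": self.n_over_r,
            "b": self.mean_set_bits,
            "dense_bits": self.dense_size_bits,
            "sparse_integers": self.sparse_size_integers,
        }


def index_stats(move_table, color_table: ColorTable, n: int | None = None) -> IndexStats:
    """Compression diagnostics: n, r, |C|, r/|C|, n/r plus color occupancy."""
    n = int(n if n is not None else move_table.n)
    r = move_table.num_runs
    c = color_table.num_colors
    freq = np.sort(color_table.color_frequencies())[::-1]
    cum = np.cumsum(freq) / r if r else freq.astype(float)
    return IndexStats(
        n=n,
        r=r,
        num_colors=c,
        runs_per_color=r / c if c else float("nan"),
        n_over_r=n / r if r else float("nan"),
        mean_set_bits=color_table.mean_set_bits,
        dense_size_bits=color_table.dense_size_bits(),
        sparse_size_integers=color_table.sparse_size_integers(),
        color_frequency=freq,
        cumulative_coverage=cum,
    )
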