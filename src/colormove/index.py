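"""High-level index construction: from reference collection to colored move table."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collection import (
    ConcatenatedText,
    ReferenceCollection,
    StrandMode,
    concatenate_documents,
)
from .colors import ColorEncoding, ColorTable, compute_run_colors, deduplicate_colors
from .move import MoveTable, build_move_table
from .suffix import (
    build_bwt,
    build_document_array,
    build_lcp,
    build_suffix_array,
    run_length_encode,
)
from .taxonomy import Taxonomy

FORMAT_VERSION = 1


@dataclass
class SuffixStructures:
    """Uncompressed build-time structures, optionally retained for oracles."""

    suffix_array: np.ndarray
    bwt: str
    lcp: np.ndarray
    doc_array: np.ndarray


@dataclass
class ColorMoveIndex:
    """A colored move-structure index plus its document catalog."""

    move: MoveTable
    colors: ColorTable
    doc_names: list[str]
    doc_taxa: list[int]
    strand_mode: StrandMode
    taxonomy: Taxonomy | None = None
    cutoff: float | None = None
    metadata: dict = field(default_factory=dict)
    full: "IndexFull | None" = None

    @property
    def n(self) -> int:
        return self.move.n

    @property
    def num_documents(self) -> int:
        return len(self.doc_names)


@dataclass
class IndexFull:
    """Text + suffix structures kept alongside the compact index.

    Needed only for exact document listing (the truth side of the color
    fidelity analysis) and for test oracles; classification itself uses just
    the move and color tables.
    """

    text: ConcatenatedText
    structures: SuffixStructures
    occ: np.ndarray = None  # (n+1, SIGMA) prefix counts over the BWT

    def __post_init__(self) -> None:
        if self.occ is None:
            from .alphabet import SIGMA, encode

            codes = encode(self.structures.bwt)
            n = len(codes)
            occ = np.zeros((n + 1, SIGMA), dtype=np.int64)
            onehot = np.zeros((n, SIGMA), dtype=np.int64)
            onehot[np.arange(n), codes.astype(np.int64)] = 1
            occ[1:] = np.cumsum(onehot, axis=0)
            self.occ = occ


def build_index(
    collection: ReferenceCollection,
    with_thresholds: bool = True,
    encoding: ColorEncoding = ColorEncoding.SPARSE,
    taxonomy: Taxonomy | None = None,
    keep_suffix_structures: bool = False,
) -> ColorMoveIndex:
    """Run the full construction pipeline for a reference collection."""
    text = concatenate_documents(collection)
    sa = build_suffix_array(text)
    bwt = build_bwt(text, sa)
    lcp = build_lcp(text, sa)
    doc_array = build_document_array(sa, text)
    runs = run_length_encode(bwt)
    move = build_move_table(runs, bwt, lcp=lcp, with_thresholds=with_thresholds)
    per_run_colors = compute_run_colors(runs, doc_array)
    colors = deduplicate_colors(per_run_colors, collection.num_documents, encoding)
    move.color_ids = colors.per_run_ids
    index = ColorMoveIndex(
        move=move,
        colors=colors,
        doc_names=[d.name for d in collection.documents],
        doc_taxa=[d.taxon_id for d in collection.documents],
        strand_mode=collection.strand_mode,
        taxonomy=taxonomy,
        metadata={
            "version": FORMAT_VERSION,
            "n": text.n,
            "r": move.num_runs,
            "num_colors": colors.num_colors,
            "num_documents": collection.num_documents,
            "strand_mode": collection.strand_mode.value,
            "with_thresholds": with_thresholds,
        },
    )
    if keep_suffix_structures:
        index.full = IndexFull(
            text=text,
            structures=SuffixStructures(sa, bwt, lcp, doc_array),
        )
    return index
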