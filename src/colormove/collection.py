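"""Reference documents and their concatenation.

A *document* is the most specific classification unit the index can report:
one genome, or a whole species' worth of genomes, depending on how the user
groups sequences.  All documents are concatenated (optionally together with
their reverse complements, under the same document ID) into a single text
terminated by ``$``, over which the BWT is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .alphabet import TERMINATOR, encode, reverse_complement, sanitize_sequence

NO_DOCUMENT = -1


class StrandMode(str, Enum):
    """Whether reverse complements are appended to the concatenation."""

    FORWARD_ONLY = "forward"
    WITH_REVERSE_COMPLEMENT = "both"


@dataclass
class Document:
    doc_id: int
    name: str
    sequences: list[str]
    taxon_id: int = -1


@dataclass
class ReferenceCollection:
    """Ordered documents plus the strand handling used at build time."""

    documents: list[Document]
    strand_mode: StrandMode = StrandMode.WITH_REVERSE_COMPLEMENT

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if ids != list(range(len(ids))):
            raise ValueError("document IDs must be 0..|D|-1 in order")

    @property
    def num_documents(self) -> int:
        return len(self.documents)

    @classmethod
    def from_sequences(
        cls,
        named_seqs: list[tuple[str, str]],
        doc_map: dict[str, str] | None = None,
        doc_taxa: dict[str, int] | None = None,
        strand_mode: StrandMode = StrandMode.WITH_REVERSE_COMPLEMENT,
    ) -> "ReferenceCollection":
        """Group named sequences into documents.

        ``doc_map`` maps sequence name -> document name; without it every
        sequence becomes its own document.  Documents are numbered in order
        of first appearance.  Sequences are sanitized (split at non-ACGT).
        """
        doc_map = doc_map or {}
        order: dict[str, Document] = {}
        for name, seq in named_seqs:
            doc_name = doc_map.get(name, name)
            if doc_name not in order:
                order[doc_name] = Document(len(order), doc_name, [])
            frags = sanitize_sequence(seq)
            if not frags:
                raise ValueError(f"sequence {name!r} empty after sanitization")
            order[doc_name].sequences.extend(frags)
        docs = list(order.values())
        if doc_taxa:
            for d in docs:
                d.taxon_id = doc_taxa.get(d.name, -1)
        return cls(docs, strand_mode)


@dataclass
class ConcatenatedText:
    """The terminated concatenation and its document boundaries.

    ``boundaries`` holds 0-based half-open ``[start, end)`` intervals, each
    mapped to a document ID; every offset below ``n - 1`` belongs to exactly
    one interval and offset ``n - 1`` is the terminator.
    """

    text: str
    boundaries: list[tuple[int, int, int]]  # (start, end, doc_id)
    codes: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.codes is None:
            self.codes = encode(self.text)

    @property
    def n(self) -> int:
        return len(self.text)

    @property
    def boundary_starts(self) -> np.ndarray:
        return np.array([b[0] for b in self.boundaries], dtype=np.int64)

    @property
    def boundary_docs(self) -> np.ndarray:
        return np.array([b[2] for b in self.boundaries], dtype=np.int64)

    def document_of(self, offset: int) -> int:
        """Document containing a text offset (NO_DOCUMENT for the terminator)."""
        if offset == self.n - 1:
            return NO_DOCUMENT
        idx = int(np.searchsorted(self.boundary_starts, offset, side="right")) - 1
        start, end, doc = self.boundaries[idx]
        if not start <= offset < end:
            raise ValueError(f"offset {offset} outside all document boundaries")
        return doc


def concatenate_documents(collection: ReferenceCollection) -> ConcatenatedText:
    """Concatenate documents in ID order and append the terminator.

    Under :attr:`StrandMode.WITH_REVERSE_COMPLEMENT` the reverse complement
    of every sequence is appended after all forward sequences, still under
    its own document's ID, so a single query pass covers both strands.
    """
    if not collection.documents:
        raise ValueError("empty reference collection")
    parts: list[str] = []
    boundaries: list[tuple[int, int, int]] = []
    pos = 0

    def _append(seq: str, doc_id: int) -> None:
        nonlocal pos
        parts.append(seq)
        boundaries.append((pos, pos + len(seq), doc_id))
        pos += len(seq)

    for doc in collection.documents:
        for seq in doc.sequences:
            if not seq:
                raise ValueError(f"document {doc.name!r} has an empty sequence")
            _append(seq, doc.doc_id)
    if collection.strand_mode is StrandMode.WITH_REVERSE_COMPLEMENT:
        for doc in collection.documents:
            for seq in doc.sequences:
                _append(reverse_complement(seq), doc.doc_id)
    parts.append(TERMINATOR)
    text = "".join(parts)
    # merge adjacent boundaries of the same document for compactness
    merged: list[tuple[int, int, int]] = []
    for start, end, doc in boundaries:
        if merged and merged[-1][2] == doc and merged[-1][1] == start:
            merged[-1] = (merged[-1][0], end, doc)
        else:
            merged.append((start, end, doc))
    return ConcatenatedText(text=text, boundaries=merged)
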