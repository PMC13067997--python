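"""Shared fixtures and brute-force oracles.

Oracles here recompute index structures directly from definitions (sorting
suffix strings, rank-counting over the raw BWT, scanning SA intervals) so
that the package's run-length / move-table code paths are checked against
an independent route.
"""

from __future__ import annotations

import numpy as np
import pytest

from colormove import (
    Document,
    ReferenceCollection,
    SimulationConfig,
    StrandMode,
    build_index,
    simulate_pangenome,
)
from colormove.collection import NO_DOCUMENT, concatenate_documents
from colormove.taxonomy import Taxonomy

# ---------------------------------------------------------------------------
# oracles


def oracle_suffix_array(text: str) -> list[int]:
    """Sort the suffix strings themselves, then recover their offsets."""
    n = len(text)
    suffixes = sorted((text[i:], i) for i in range(n))
    return [i for _, i in suffixes]


def oracle_bwt(text: str) -> str:
    """Sort all cyclic rotations; take the last column."""
    rotations = sorted(text[i:] + text[:i] for i in range(len(text)))
    return "".join(rot[-1] for rot in rotations)


def oracle_lcp(text: str, sa: list[int]) -> list[int]:
    out = [0]
    for prev, cur in zip(sa, sa[1:]):
        a, b = text[prev:], text[cur:]
        k = 0
        while k < min(len(a), len(b)) and a[k] == b[k]:
            k += 1
        out.append(k)
    return out


def oracle_lf(bwt: str) -> list[int]:
    """Rank-based LF over the raw BWT: LF(i) = C[c] + rank_c(i)."""
    counts: dict[str, int] = {}
    for ch in bwt:
        counts[ch] = counts.get(ch, 0) + 1
    cbase = {}
    total = 0
    for ch in sorted(counts):
        cbase[ch] = total
        total += counts[ch]
    seen: dict[str, int] = {}
    out = []
    for ch in bwt:
        out.append(cbase[ch] + seen.get(ch, 0))
        seen[ch] = seen.get(ch, 0) + 1
    return out


def oracle_run_colors(bwt: str, doc_array) -> list[frozenset]:
    """Distinct documents per maximal run, scanned directly."""
    colors = []
    i = 0
    while i < len(bwt):
        j = i
        while j < len(bwt) and bwt[j] == bwt[i]:
            j += 1
        colors.append(
            frozenset(int(d) for d in doc_array[i:j] if d != NO_DOCUMENT)
        )
        i = j
    return colors


def oracle_reposition_direction(
    text: str, sa: list[int], bwt: str, row: int, char: str
) -> str | None:
    """'up'/'down' by direct LCP comparison of candidate rows; None if absent.

    Ties (equal LCP both ways) break upward, matching the index contract.
    """
    up = next((i for i in range(row - 1, -1, -1) if bwt[i] == char), None)
    down = next((i for i in range(row + 1, len(bwt)) if bwt[i] == char), None)
    if up is None and down is None:
        return None
    if down is None:
        return "up"
    if up is None:
        return "down"

    def lcp_with(other: int) -> int:
        a, b = text[sa[row]:], text[sa[other]:]
        k = 0
        while k < min(len(a), len(b)) and a[k] == b[k]:
            k += 1
        return k

    return "up" if lcp_with(up) >= lcp_with(down) else "down"


def oracle_matching_statistic(read: str, text: str, k: int) -> int:
    """Length of the longest prefix of read[k:] occurring in text."""
    lo, hi = 0, len(read) - k
    best = 0
    for length in range(1, len(read) - k + 1):
        if read[k : k + length] in text:
            best = length
        else:
            break
    return best


def random_collection(
    rng: np.random.Generator,
    max_docs: int = 4,
    max_len: int = 120,
    repetitive: bool | None = None,
) -> ReferenceCollection:
    """A small random collection, sometimes with near-identical documents."""
    num_docs = int(rng.integers(1, max_docs + 1))
    strand = (
        StrandMode.WITH_REVERSE_COMPLEMENT
        if rng.random() < 0.5
        else StrandMode.FORWARD_ONLY
    )
    if repetitive is None:
        repetitive = bool(rng.random() < 0.5)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    docs = []
    if repetitive:
        length = int(rng.integers(5, max_len))
        base = bases[rng.integers(0, 4, size=length)]
        for d in range(num_docs):
            seq = base.copy()
            sites = rng.random(length) < 0.05
            seq[sites] = bases[rng.integers(0, 4, size=int(sites.sum()))]
            docs.append(Document(d, f"D{d}", [seq.tobytes().decode()]))
    else:
        for d in range(num_docs):
            length = int(rng.integers(5, max_len))
            seq = bases[rng.integers(0, 4, size=length)]
            docs.append(Document(d, f"D{d}", [seq.tobytes().decode()]))
    return ReferenceCollection(docs, strand)


def random_read(rng: np.random.Generator, length: int) -> str:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bases[rng.integers(0, 4, size=length)].tobytes().decode()


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def toy_taxonomy() -> Taxonomy:
    # root(1) -> genus(10) -> species 101, 102
    return Taxonomy(
        parents={1: 1, 10: 1, 101: 10, 102: 10},
        ranks={1: "root", 10: "genus", 101: "species", 102: "species"},
        names={1: "root", 10: "genusA", 101: "sp1", 102: "sp2"},
    )


@pytest.fixture(scope="session")
def toy_collection(toy_taxonomy) -> ReferenceCollection:
    return ReferenceCollection(
        [
            Document(0, "D1", ["AAC"], taxon_id=101),
            Document(1, "D2", ["AAG"], taxon_id=102),
        ],
        StrandMode.FORWARD_ONLY,
    )


@pytest.fixture(scope="session")
def toy_index(toy_collection, toy_taxonomy):
    return build_index(
        toy_collection, taxonomy=toy_taxonomy, keep_suffix_structures=True
    )


@pytest.fixture(scope="session")
def toy_text(toy_collection):
    return concatenate_documents(toy_collection)


# Desk-scale pangenome shared by the classification/fidelity tests: 6
# species x 4 genomes (3 indexed + 1 held out) of 8 kb, reads of 1 kb.
# Documents are species-level (all indexed genomes of a species form one
# document), the granularity used for taxonomic classification.
PANGENOME_TEST_CONFIG = SimulationConfig(
    seed=11,
    num_species=6,
    genomes_per_species=4,
    genome_length=8_000,
    read_length_mean=1_000.0,
    document_level="species",
)


@pytest.fixture(scope="session")
def pangenome_sim():
    return simulate_pangenome(PANGENOME_TEST_CONFIG)


@pytest.fixture(scope="session")
def pangenome_index(pangenome_sim):
    return build_index(
        pangenome_sim.collection,
        taxonomy=pangenome_sim.taxonomy,
        keep_suffix_structures=True,
    )
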