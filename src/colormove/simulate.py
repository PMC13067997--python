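"""Synthetic pangenomes, taxonomies and error-bearing reads.

The generator emulates the structure the index is designed for: a set of
species, each represented by several near-identical genomes (redundancy)
and separated from other species by a larger divergence (variability).  A
root ancestor sequence is mutated into per-species ancestors at the
inter-species rate, and each genome is an intra-species-rate mutation of
its species ancestor.  One genome per species is held out of the index and
used to simulate positive reads — reads from strains the index has never
seen, though their species is represented.  Null reads come from an
independently drawn clade that shares no ancestry with the index.

Evolution is substitution-only (no structural variants); this is enough to
create realistic run/color structure, though real pangenomes also contain
indels, rearrangements and horizontal transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import reverse_complement
from .collection import Document, ReferenceCollection, StrandMode
from .taxonomy import Taxonomy

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.int64)
_BASE_INDEX[_BASES] = np.arange(4)

ROOT_TAXON = 1


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pangenome and read sets.

    Defaults describe a desk-scale pangenome: 10 species of 20 kb genomes,
    5 genomes each (one held out per species), 0.1% within-species and 5%
    between-species divergence, and 2 kb reads carrying 5% substitution
    errors (ONT-like error level; indel rates are available but default to
    zero so error placement stays position-exact).
    """

    seed: int = 0
    num_species: int = 10
    genomes_per_species: int = 5
    genome_length: int = 20_000
    inter_species_divergence: float = 0.05
    intra_species_divergence: float = 0.001
    species_per_genus: int = 2
    read_length_mean: float = 2_000.0
    read_length_sd: float = 0.0
    error_substitution: float = 0.05
    error_insertion: float = 0.0
    error_deletion: float = 0.0
    null_divergence: float = 0.05
    # "genome": every indexed genome is its own document (multi-class use);
    # "species": all indexed genomes of a species form one document, the
    # granularity used for taxonomic classification and color fidelity
    document_level: str = "genome"

    def __post_init__(self) -> None:
        for name in (
            "inter_species_divergence",
            "intra_species_divergence",
            "error_substitution",
            "error_insertion",
            "error_deletion",
            "null_divergence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.num_species < 1 or self.genomes_per_species < 1:
            raise ValueError("need at least one species and one genome")
        if self.genome_length < 1 or self.read_length_mean <= 0:
            raise ValueError("lengths must be positive")
        if self.document_level not in ("genome", "species"):
            raise ValueError("document_level must be 'genome' or 'species'")


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    source: str
    taxon_id: int | None  # None marks a null read


@dataclass
class PangenomeSimulation:
    """Indexed collection, taxonomy, held-out genomes and the truth map."""

    collection: ReferenceCollection
    taxonomy: Taxonomy
    held_out: list[tuple[str, str, int]]  # (name, sequence, species taxon)
    config: SimulationConfig
    species_taxa: list[int] = field(default_factory=list)


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability ``rate``."""
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    sites = np.flatnonzero(rng.random(len(seq)) < rate)
    if len(sites):
        # shift to a uniformly random *different* base
        shift = rng.integers(1, 4, size=len(sites))
        out[sites] = _BASES[(_BASE_INDEX[out[sites]] + shift) % 4]
    return out


def species_taxon_id(species: int) -> int:
    return 1000 + species


def genus_taxon_id(genus: int) -> int:
    return 100 + genus


def build_taxonomy(num_species: int, species_per_genus: int) -> Taxonomy:
    """Two-level taxonomy: species grouped into genera under one root."""
    parents = {ROOT_TAXON: ROOT_TAXON}
    ranks = {ROOT_TAXON: "root"}
    names = {ROOT_TAXON: "root"}
    for s in range(num_species):
        g = s // species_per_genus
        gid = genus_taxon_id(g)
        if gid not in parents:
            parents[gid] = ROOT_TAXON
            ranks[gid] = "genus"
            names[gid] = f"genus{g}"
        sid = species_taxon_id(s)
        parents[sid] = gid
        ranks[sid] = "species"
        names[sid] = f"species{s}"
    return Taxonomy(parents, ranks, names)


def simulate_pangenome(config: SimulationConfig) -> PangenomeSimulation:
    """Generate the indexed collection, taxonomy and held-out genomes.

    With ``genomes_per_species`` = g, genomes 0..g-2 of each species are
    indexed (each as its own document, mapped to the species taxon) and the
    last genome is held out for positive-read simulation.  With g = 1 the
    single genome is both indexed and used as the read source.
    """
    rng = np.random.default_rng([config.seed, 0])
    ancestor = _random_genome(rng, config.genome_length)
    taxonomy = build_taxonomy(config.num_species, config.species_per_genus)
    documents: list[Document] = []
    held_out: list[tuple[str, str, int]] = []
    species_taxa = []
    for s in range(config.num_species):
        sp_ancestor = _mutate(ancestor, config.inter_species_divergence, rng)
        taxon = species_taxon_id(s)
        species_taxa.append(taxon)
        genomes = [
            _mutate(sp_ancestor, config.intra_species_divergence, rng)
            for _ in range(config.genomes_per_species)
        ]
        indexed = genomes[:-1] if len(genomes) > 1 else genomes
        if config.document_level == "species":
            documents.append(
                Document(
                    doc_id=len(documents),
                    name=f"sp{s}",
                    sequences=[g.tobytes().decode("ascii") for g in indexed],
                    taxon_id=taxon,
                )
            )
        else:
            for g, genome in enumerate(indexed):
                documents.append(
                    Document(
                        doc_id=len(documents),
                        name=f"sp{s}_g{g}",
                        sequences=[genome.tobytes().decode("ascii")],
                        taxon_id=taxon,
                    )
                )
        held = genomes[-1]
        held_out.append((f"sp{s}_heldout", held.tobytes().decode("ascii"), taxon))
    collection = ReferenceCollection(documents, StrandMode.WITH_REVERSE_COMPLEMENT)
    return PangenomeSimulation(collection, taxonomy, held_out, config, species_taxa)


def simulate_null_genomes(
    config: SimulationConfig, num_genomes: int = 5
) -> list[tuple[str, str, None]]:
    """An unrelated clade: fresh random ancestor, diversified at the null rate."""
    rng = np.random.default_rng([config.seed, 1])
    ancestor = _random_genome(rng, config.genome_length)
    out = []
    for i in range(num_genomes):
        g = _mutate(ancestor, config.null_divergence, rng)
        out.append((f"null_g{i}", g.tobytes().decode("ascii"), None))
    return out


def _apply_errors(
    seq: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    ps, pi, pd = (
        config.error_substitution,
        config.error_insertion,
        config.error_deletion,
    )
    if ps > 0:
        seq = _mutate(seq, ps, rng)
    if pi <= 0 and pd <= 0:
        return seq
    out = bytearray()
    u = rng.random(2 * len(seq))
    ui = 0
    for b in seq:
        if u[ui] < pd:  # deletion
            ui += 2
            continue
        out.append(b)
        if u[ui + 1] < pi:  # insertion after the base
            out.append(int(_BASES[rng.integers(0, 4)]))
        ui += 2
    if not out:
        out.append(int(_BASES[rng.integers(0, 4)]))
    return np.frombuffer(bytes(out), dtype=np.uint8)


def simulate_reads(
    sources: list[tuple[str, str, int | None]],
    config: SimulationConfig,
    num_reads: int,
    seed_stream: int = 2,
    both_strands: bool = True,
) -> list[SimulatedRead]:
    """Draw error-bearing reads from (name, sequence, taxon) sources.

    Read lengths follow a normal distribution truncated to [50, source
    length]; reads come from either strand when ``both_strands`` (matching
    an index that includes reverse complements).
    """
    if not sources:
        raise ValueError("no source genomes")
    rng = np.random.default_rng([config.seed, seed_stream])
    reads: list[SimulatedRead] = []
    for i in range(num_reads):
        name, seq, taxon = sources[int(rng.integers(len(sources)))]
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        length = int(round(rng.normal(config.read_length_mean, config.read_length_sd)))
        length = max(50, min(length, len(raw)))
        if length > len(raw):
            raise ValueError(f"read longer than source genome {name!r}")
        start = int(rng.integers(0, len(raw) - length + 1))
        fragment = raw[start : start + length]
        fragment = _apply_errors(fragment, config, rng)
        read_seq = fragment.tobytes().decode("ascii")
        if both_strands and rng.random() < 0.5:
            read_seq = reverse_complement(read_seq)
        reads.append(SimulatedRead(f"read_{i}_{name}", read_seq, name, taxon))
    return reads
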