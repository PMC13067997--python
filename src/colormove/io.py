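"""File formats: FASTA/FASTQ input, TSV maps and reports, index directories.

The index is serialized as a versioned directory of ``.npy`` arrays plus a
JSON metadata file; serialization is deterministic, so re-saving an
unchanged bundle reproduces identical bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .classify import ClassificationRecord
from .collection import StrandMode
from .colors import ColorEncoding, ColorTable
from .index import FORMAT_VERSION, ColorMoveIndex
from .move import MoveTable
from .taxonomy import Taxonomy


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Named sequences in file order, upper-cased."""
    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read IDs and sequences (qualities ignored), upper-cased."""
    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")
    ]
    if not records:
        raise ValueError(f"no FASTQ records in {path}")
    return records


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Dispatch on extension: .fq/.fastq as FASTQ, otherwise FASTA."""
    suffix = Path(path).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_two_column_tsv(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, value = line.split("\t")[:2]
        out[key] = value
    return out


def read_truth(path: str | Path) -> dict[str, int | None]:
    """Truth table read_id -> taxon ID, with ``null`` marking off-index reads."""
    raw = read_two_column_tsv(path)
    return {
        k: (None if v.lower() in {"null", "-", "none", ""} else int(v))
        for k, v in raw.items()
    }


def write_truth(truths: dict[str, int | None], path: str | Path) -> None:
    lines = [f"{k}\t{'null' if v is None else v}" for k, v in truths.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# -- classification reports --------------------------------------------------

REPORT_COLUMNS = (
    "read_id",
    "status",
    "taxon_id",
    "taxon_rank",
    "average_pml",
    "documents",
    "scores",
)


def write_report(
    records: list[ClassificationRecord],
    path: str | Path,
    doc_names: list[str] | None = None,
    top_scores: int = 5,
) -> None:
    """One TSV row per read; unclassified reads leave taxon fields empty."""

    def name(d: int) -> str:
        return doc_names[d] if doc_names else str(d)

    lines = ["\t".join(REPORT_COLUMNS)]
    for rec in records:
        top = sorted(rec.scores.items(), key=lambda ds: (-ds[1], ds[0]))[:top_scores]
        lines.append(
            "\t".join(
                [
                    rec.read_id,
                    rec.status,
                    "" if rec.taxon_id is None else str(rec.taxon_id),
                    rec.taxon_rank,
                    f"{rec.average_pml:.6f}",
                    ",".join(name(d) for d in rec.documents),
                    ",".join(f"{name(d)}:{s}" for d, s in top),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_report(path: str | Path) -> list[dict]:
    """Parse a report TSV back into dictionaries (evaluation input)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != list(REPORT_COLUMNS):
        raise ValueError(f"not a classification report: {path}")
    out = []
    for line in lines[1:]:
        fields = line.split("\t")
        row = dict(zip(REPORT_COLUMNS, fields))
        row["taxon_id"] = int(row["taxon_id"]) if row["taxon_id"] else None
        row["average_pml"] = float(row["average_pml"])
        row["documents"] = row["documents"].split(",") if row["documents"] else []
        out.append(row)
    return out


def write_kraken_style(records: list[ClassificationRecord], path: str | Path) -> None:
    """Two-column interoperability summary: C/U, read ID, taxon (0 if none)."""
    lines = [
        f"{rec.status}\t{rec.read_id}\t{rec.taxon_id if rec.taxon_id is not None else 0}"
        for rec in records
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- index serialization ------------------------------------------------------


def save_index(index: ColorMoveIndex, directory: str | Path) -> None:
    """Write the compact index (move table, colors, catalog, taxonomy)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    move = index.move
    np.save(d / "char_codes.npy", move.char_codes)
    np.save(d / "lengths.npy", move.lengths)
    np.save(d / "dest_run.npy", move.dest_run)
    np.save(d / "dest_offset.npy", move.dest_offset)
    np.save(d / "above.npy", move.above)
    np.save(d / "below.npy", move.below)
    if move.thresholds is not None:
        np.save(d / "thresholds.npy", move.thresholds)
    np.save(d / "color_per_run.npy", index.colors.per_run_ids)
    flat = np.array(
        [doc for color in index.colors.colors for doc in sorted(color)],
        dtype=np.int64,
    )
    offsets = np.cumsum([0] + [len(c) for c in index.colors.colors]).astype(np.int64)
    np.save(d / "color_docs_flat.npy", flat)
    np.save(d / "color_offsets.npy", offsets)
    if index.taxonomy is not None:
        index.taxonomy.to_tsv(d / "taxonomy.tsv")
    meta = dict(index.metadata)
    meta.update(
        {
            "version": FORMAT_VERSION,
            "doc_names": index.doc_names,
            "doc_taxa": index.doc_taxa,
            "strand_mode": index.strand_mode.value,
            "cutoff": index.cutoff,
            "encoding": index.colors.encoding.value,
            "has_taxonomy": index.taxonomy is not None,
            "with_thresholds": move.thresholds is not None,
        }
    )
    (d / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def load_index(directory: str | Path) -> ColorMoveIndex:
    d = Path(directory)
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"not an index directory: {directory}")
    meta = json.loads(meta_path.read_text())
    if meta.get("version") != FORMAT_VERSION:
        raise ValueError(
            f"index format version {meta.get('version')} != {FORMAT_VERSION}"
        )
    required = [
        "char_codes",
        "lengths",
        "dest_run",
        "dest_offset",
        "above",
        "below",
        "color_per_run",
        "color_docs_flat",
        "color_offsets",
    ]
    arrays = {}
    for name in required:
        path = d / f"{name}.npy"
        if not path.exists():
            raise FileNotFoundError(f"index component missing: {path.name}")
        arrays[name] = np.load(path)
    lengths = arrays["lengths"]
    starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    thresholds = None
    if meta.get("with_thresholds"):
        thresholds = np.load(d / "thresholds.npy")
    move = MoveTable(
        char_codes=arrays["char_codes"],
        lengths=lengths,
        starts=starts,
        dest_run=arrays["dest_run"],
        dest_offset=arrays["dest_offset"],
        above=arrays["above"],
        below=arrays["below"],
        thresholds=thresholds,
        color_ids=arrays["color_per_run"],
    )
    offsets = arrays["color_offsets"]
    flat = arrays["color_docs_flat"]
    colors = [
        frozenset(int(x) for x in flat[offsets[i] : offsets[i + 1]])
        for i in range(len(offsets) - 1)
    ]
    color_table = ColorTable(
        colors=colors,
        per_run_ids=arrays["color_per_run"],
        num_documents=len(meta["doc_names"]),
        encoding=ColorEncoding(meta.get("encoding", "sparse")),
    )
    taxonomy = None
    if meta.get("has_taxonomy"):
        taxonomy = Taxonomy.from_tsv(d / "taxonomy.tsv")
    return ColorMoveIndex(
        move=move,
        colors=color_table,
        doc_names=list(meta["doc_names"]),
        doc_taxa=list(meta["doc_taxa"]),
        strand_mode=StrandMode(meta["strand_mode"]),
        taxonomy=taxonomy,
        cutoff=meta.get("cutoff"),
        metadata=meta,
    )
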