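"""Shared record types and I/O for the formats the pipeline touches.

Coordinates are 0-based half-open throughout. Amino-acid sequences are the
20 standard letters plus X; other ambiguity codes are mapped to X with a
warning so the scoring alphabet stays closed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
_VALID = set(ALPHABET)


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class ReferentialIntegrityError(KeyError):
    """Annotation rows reference proteins absent from the FASTA input."""


@dataclass
class ProteinRecord:
    """One amino-acid sequence with its gene's genomic context."""

    protein_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"{self.protein_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if len(self.sequence) < 1:
            raise ValueError(f"{self.protein_id}: empty sequence")
        self.sequence = sanitize_sequence(self.sequence, self.protein_id)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """Upstream locus-caller annotation for one gene.

    ``annotation_evalue`` is None exactly when the caller labelled the gene
    "Unknown" (it then has no score to report).
    """

    protein_id: str
    locus_id: str | None
    annotation_label: str
    annotation_evalue: float | None
    subtype: str | None

    def __post_init__(self) -> None:
        if (self.annotation_evalue is None) != (self.annotation_label == "Unknown"):
            raise ValueError(
                f"{self.protein_id}: annotation_evalue must be null iff label is 'Unknown' "
                f"(got label={self.annotation_label!r}, evalue={self.annotation_evalue!r})"
            )


@dataclass
class LocusRecord:
    """One CRISPR locus: its subtype, operon span and member genes."""

    locus_id: str
    genome_id: str
    subtype: str
    contig_id: str
    operon_start: int
    operon_end: int
    member_proteins: list[str] = field(default_factory=list)
    cas10_id: str | None = None

    def __post_init__(self) -> None:
        if self.operon_end <= self.operon_start:
            raise ValueError(f"{self.locus_id}: operon_end must exceed operon_start")


def sanitize_sequence(seq: str, name: str = "?") -> str:
    """Uppercase, strip terminal '*' stops, map non-standard residues to X."""
    s = seq.upper().rstrip("*").lstrip("*")
    if not set(s) <= _VALID:
        bad = sorted(set(s) - _VALID)
        warnings.warn(
            f"{name}: ambiguous residues {bad} mapped to X", stacklevel=2
        )
        s = "".join(c if c in _VALID else "X" for c in s)
    return s


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are uppercased and terminal stop characters stripped. Raises
    :class:`FastaParseError` on records with empty ids or empty sequences.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, rec in _iter_fasta(fh):
            rid, seq = rec
            if not rid:
                raise FastaParseError(f"{path}:{lineno}: header with empty id")
            if not seq:
                raise FastaParseError(f"{path}:{lineno}: record '{rid}' has no sequence")
            out.append((rid, sanitize_sequence(seq, rid)))
    return out


def _iter_fasta(fh) -> Iterable[tuple[int, tuple[str, str]]]:
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if header is not None:
                yield header_line, (header, "".join(chunks))
            header = line[1:].split()[0] if line[1:].strip() else ""
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise FastaParseError(f"line {lineno}: sequence data before first header")
            chunks.append(line.strip())
    if header is not None:
        yield header_line, (header, "".join(chunks))


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA (60-column wrap)."""
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


# Columns the annotation table must provide; extra columns are ignored.
ANNOTATION_COLUMNS = [
    "protein_id",
    "genome_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "locus_id",
    "annotation_label",
    "annotation_evalue",
    "subtype",
]


def read_annotation_table(
    path: str | Path, fasta_records: Sequence[tuple[str, str]]
) -> list[tuple[ProteinRecord, GeneAnnotation]]:
    """Read the TSV annotation table and join it to FASTA sequences.

    The table is the pipeline's contract with an upstream locus caller:
    one row per gene, header row naming at least protein_id, genome_id,
    contig_id, start, end, strand, locus_id, annotation_label,
    annotation_evalue and subtype. Empty strings in nullable columns
    (locus_id, annotation_evalue, subtype) become None.

    Raises :class:`ReferentialIntegrityError` listing every protein_id in
    the table that is absent from the FASTA input.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    seqs = dict(fasta_records)
    absent = [pid for pid in df["protein_id"] if pid not in seqs]
    if absent:
        raise ReferentialIntegrityError(
            f"annotation table references proteins absent from FASTA: {sorted(set(absent))}"
        )
    out = []
    for row in df.itertuples(index=False):
        protein = ProteinRecord(
            protein_id=row.protein_id,
            genome_id=row.genome_id,
            contig_id=row.contig_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            sequence=seqs[row.protein_id],
        )
        ann = GeneAnnotation(
            protein_id=row.protein_id,
            locus_id=row.locus_id or None,
            annotation_label=row.annotation_label,
            annotation_evalue=float(row.annotation_evalue) if row.annotation_evalue else None,
            subtype=row.subtype or None,
        )
        out.append((protein, ann))
    return out


def write_census(table: pd.DataFrame, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write the per-locus census as TSV plus a byte-stable JSON mirror.

    Expects one row per locus with columns locus_id, genome_id, subtype,
    has_cyclase, has_hd, families, activators, n_type3_loci_in_genome.
    Set-valued columns are serialized as comma-joined sorted strings; loci
    with no effectors get an empty field, never a dropped row.
    """
    df = table.copy()
    for col in ("families", "activators", "candidates"):
        if col in df.columns:
            df[col] = df[col].map(lambda v: ",".join(sorted(v)) if isinstance(v, (set, frozenset, list, tuple)) else (v or ""))
    df = df.sort_values("locus_id").reset_index(drop=True)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = df.to_dict(orient="records")
        Path(json_path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
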