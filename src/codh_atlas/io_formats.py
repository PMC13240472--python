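"""Typed readers and writers for the tabular and sequence formats the pipeline consumes.

All tables are UTF-8, tab-separated. Context, HMM-hit and sample-metadata
tables carry a header row; the 12-column homology-hit table follows the
headerless BLAST/DIAMOND ``outfmt 6`` convention. Coordinates are 1-based
inclusive throughout (GenBank convention). Parsers are strict: invalid rows
raise :class:`ParseError` naming the offending line rather than coercing.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# 20 canonical amino acids plus X for ambiguity; motif and ligand rules are
# defined on canonical letters, so anything else is rejected at parse time.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = AMINO_ACIDS | {"X"}


class ParseError(ValueError):
    """Raised when an input file violates the expected format or an invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """One candidate CODH amino-acid sequence with provenance."""

    id: str
    sequence: str
    description: str = ""
    source_db: str = "synthetic"  # one of {nr, refseq, synthetic}

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("protein record must have a non-empty id")
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ParseError(
                f"record {self.id!r}: non-canonical residues {sorted(bad)} "
                "(allowed: 20 canonical amino acids plus X)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRow:
    """One row of 12-column BLAST/DIAMOND tabular output (``outfmt 6``)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ParseError(f"hit {self.query_id}->{self.subject_id}: pct_identity outside [0, 100]")
        if self.aln_len < 1:
            raise ParseError(f"hit {self.query_id}->{self.subject_id}: aln_len < 1")
        if self.qstart > self.qend:
            raise ParseError(f"hit {self.query_id}->{self.subject_id}: qstart > qend")
        if self.evalue < 0:
            raise ParseError(f"hit {self.query_id}->{self.subject_id}: negative e-value")
        if self.bitscore < 0:
            raise ParseError(f"hit {self.query_id}->{self.subject_id}: negative bit score")


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence in a genome-context table."""

    genome_id: str
    contig_id: str
    cds_index: int
    start: int
    end: int
    strand: str
    product: str = ""
    cog_id: Optional[str] = None
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParseError(f"CDS {self.genome_id}/{self.contig_id}/{self.cds_index}: start > end")
        if self.strand not in {"+", "-"}:
            raise ParseError(f"CDS {self.genome_id}/{self.contig_id}/{self.cds_index}: strand must be + or -")


@dataclass(frozen=True)
class HmmHitRow:
    """One reduced profile-HMM hit (target, profile, e-value, target length)."""

    target_id: str
    profile_id: str
    evalue: float
    target_len: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ParseError(f"HMM hit {self.target_id}: negative e-value")
        if self.target_len < 1:
            raise ParseError(f"HMM hit {self.target_id}: target_len < 1")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample covariates for abundance profiling.

    ``o2_uM`` may be missing: for several habitats only depth is recorded,
    and depth then serves as the oxygen-availability proxy.
    """

    sample_id: str
    total_reads: int
    depth_m: Optional[float] = None
    o2_uM: Optional[float] = None
    habitat: str = ""

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ParseError(f"sample {self.sample_id}: total_reads must be positive")
        if self.depth_m is not None and self.depth_m < 0:
            raise ParseError(f"sample {self.sample_id}: negative depth")
        if self.o2_uM is not None and self.o2_uM < 0:
            raise ParseError(f"sample {self.sample_id}: negative O2 concentration")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, source_db: str = "synthetic") -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased; duplicate ids and non-canonical residues are
    rejected. An empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper().replace("*", ""),
                description=desc,
                source_db=source_db,
            )
        )
    if not records:
        warnings.warn(f"{path}: no sequences found", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# 12-column homology hit table (headerless outfmt 6)
# ---------------------------------------------------------------------------

_ALN_COLS = 12


def read_alignment_table(path: str | Path) -> list[AlignmentRow]:
    """Read a 12-column BLAST/DIAMOND tabular file.

    Exactly 12 tab-separated columns per row; anything else raises
    :class:`ParseError` naming the row.
    """
    path = Path(path)
    rows: list[AlignmentRow] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, parts in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not parts or (len(parts) == 1 and not parts[0].strip()):
                continue
            if len(parts) != _ALN_COLS:
                raise ParseError(f"{path}:{lineno}: expected {_ALN_COLS} columns, found {len(parts)}")
            try:
                rows.append(
                    AlignmentRow(
                        query_id=parts[0],
                        subject_id=parts[1],
                        pct_identity=float(parts[2]),
                        aln_len=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        qstart=int(parts[6]),
                        qend=int(parts[7]),
                        sstart=int(parts[8]),
                        send=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_alignment_table(rows: Iterable[AlignmentRow], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for r in rows:
            w.writerow([
                r.query_id, r.subject_id, f"{r.pct_identity:g}", r.aln_len,
                r.mismatches, r.gap_opens, r.qstart, r.qend, r.sstart, r.send,
                f"{r.evalue:g}", f"{r.bitscore:g}",
            ])


# ---------------------------------------------------------------------------
# Headered TSVs: context tables, HMM hits, sample metadata
# ---------------------------------------------------------------------------

_CTX_HEADER = ["genome_id", "contig_id", "cds_index", "start", "end",
               "strand", "product", "cog_id", "protein_id"]
_HMM_HEADER = ["target_id", "profile_id", "evalue", "target_len"]
_META_HEADER = ["sample_id", "depth_m", "o2_uM", "total_reads", "habitat"]


def _read_headered(path: Path, expected_header: list[str]) -> Iterable[tuple[int, dict[str, str]]]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, header row required") from None
        if header != expected_header:
            raise ParseError(
                f"{path}: header mismatch, expected {expected_header}, found {header}"
            )
        for lineno, parts in enumerate(reader, start=2):
            if not parts or (len(parts) == 1 and not parts[0].strip()):
                continue
            if len(parts) != len(expected_header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(expected_header)} columns, found {len(parts)}"
                )
            yield lineno, dict(zip(expected_header, parts))


def read_context_table(path: str | Path) -> list[CdsRecord]:
    """Read a genome-context CDS table; cds_index must be strictly increasing
    within each contig (row order is positional order)."""
    path = Path(path)
    records: list[CdsRecord] = []
    last_index: dict[tuple[str, str], int] = {}
    for lineno, row in _read_headered(path, _CTX_HEADER):
        try:
            rec = CdsRecord(
                genome_id=row["genome_id"],
                contig_id=row["contig_id"],
                cds_index=int(row["cds_index"]),
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                product=row["product"],
                cog_id=row["cog_id"] or None,
                protein_id=row["protein_id"] or None,
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        key = (rec.genome_id, rec.contig_id)
        if key in last_index and rec.cds_index <= last_index[key]:
            raise ParseError(
                f"{path}:{lineno}: cds_index not strictly increasing on contig {rec.contig_id!r}"
            )
        last_index[key] = rec.cds_index
        records.append(rec)
    return records


def write_context_table(records: Iterable[CdsRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_CTX_HEADER)
        for r in records:
            w.writerow([r.genome_id, r.contig_id, r.cds_index, r.start, r.end,
                        r.strand, r.product, r.cog_id or "", r.protein_id or ""])


def read_hmm_hits(path: str | Path) -> list[HmmHitRow]:
    path = Path(path)
    rows: list[HmmHitRow] = []
    for lineno, row in _read_headered(path, _HMM_HEADER):
        try:
            rows.append(
                HmmHitRow(
                    target_id=row["target_id"],
                    profile_id=row["profile_id"],
                    evalue=float(row["evalue"]),
                    target_len=int(row["target_len"]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_hmm_hits(rows: Iterable[HmmHitRow], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_HMM_HEADER)
        for r in rows:
            w.writerow([r.target_id, r.profile_id, f"{r.evalue:g}", r.target_len])


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    path = Path(path)
    rows: list[SampleMetadata] = []
    for lineno, row in _read_headered(path, _META_HEADER):
        try:
            rows.append(
                SampleMetadata(
                    sample_id=row["sample_id"],
                    depth_m=float(row["depth_m"]) if row["depth_m"] else None,
                    o2_uM=float(row["o2_uM"]) if row["o2_uM"] else None,
                    total_reads=int(row["total_reads"]),
                    habitat=row["habitat"],
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return rows


def write_sample_metadata(rows: Iterable[SampleMetadata], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_META_HEADER)
        for r in rows:
            w.writerow([
                r.sample_id,
                "" if r.depth_m is None else f"{r.depth_m:g}",
                "" if r.o2_uM is None else f"{r.o2_uM:g}",
                r.total_reads,
                r.habitat,
            ])
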