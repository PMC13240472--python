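"""Short-read abundance statistics for CODH genes.

Per-read best hits against a protein reference database are filtered by a
minimum amino-acid alignment length of 32 residues and gene-specific percent
identity (60% for Mo-CODH coxL; 50% for Ni-CODH cooS and cdhA and for the
ribosomal markers); all thresholds inclusive. Retained counts are normalised
to RPKM (reads per kilobase of gene per million sequenced reads); the
"average gene copies per organism" divides a gene's RPKM by the mean RPKM of
14 universal single-copy ribosomal proteins, so a value of 0.1 means one in
ten community members carries the gene. The Mo/Ni ratio per sample is
copies(coxL) / (copies(cooS) + copies(cdhA)) and is reported as undefined
(not infinity) when the denominator is zero.

Reference gene lengths are in nucleotides; where only protein references
exist, 3x the protein length is used (reads are nucleotide, the database is
protein, as in DIAMOND blastx searches).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io_formats import AlignmentRow, SampleMetadata

MIN_ALN_LEN = 32
DEFAULT_MIN_IDENTITY = {"coxL": 60.0, "cooS": 50.0, "cdhA": 50.0, "ribosomal_marker": 50.0}
DEFAULT_MARKER_COUNT = 14


@dataclass(frozen=True)
class GeneClass:
    """One reference gene class with its length and identity threshold."""

    name: str          # coxL | cooS | cdhA | ribosomal_marker
    ref_len_bp: int
    min_identity: float = 50.0

    def __post_init__(self) -> None:
        if self.ref_len_bp <= 0:
            raise ValueError(f"gene class {self.name}: ref_len_bp must be positive")
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError(f"gene class {self.name}: min_identity outside [0, 100]")


@dataclass
class AbundanceProfile:
    """Per-sample abundance summary."""

    sample_id: str
    rpkm: dict[str, float] = field(default_factory=dict)
    copies: dict[str, float] = field(default_factory=dict)   # Mo, Ni_cooS, Ni_cdhA, Ni_total
    ratio_mo_ni: Optional[float] = None
    depth_m: Optional[float] = None
    o2_uM: Optional[float] = None


def best_hit_per_read(rows: Sequence[AlignmentRow]) -> list[AlignmentRow]:
    """One row per query: highest bit score, ties by lower e-value, then
    first occurrence."""
    best: dict[str, tuple[float, float, int]] = {}
    keep: dict[str, AlignmentRow] = {}
    for i, row in enumerate(rows):
        key = (-row.bitscore, row.evalue, i)
        if row.query_id not in best or key < best[row.query_id]:
            best[row.query_id] = key
            keep[row.query_id] = row
    return [keep[q] for q in keep]


def filter_read_hits(
    rows: Sequence[AlignmentRow],
    subject_class: Mapping[str, GeneClass],
) -> tuple[list[AlignmentRow], int]:
    """Apply the alignment-length and gene-specific identity filters.

    ``rows`` must already be best-hit-per-read. A row is retained iff
    aln_len >= 32 and pct_identity >= its gene class threshold (inclusive).
    Rows whose subject is in no gene class are dropped; their count is
    returned for logging.
    """
    retained: list[AlignmentRow] = []
    unknown = 0
    for row in rows:
        cls = subject_class.get(row.subject_id)
        if cls is None:
            unknown += 1
            continue
        if row.aln_len >= MIN_ALN_LEN and row.pct_identity >= cls.min_identity:
            retained.append(row)
    return retained, unknown


def rpkm(count: int, ref_len_bp: int, total_reads: int) -> float:
    """Reads per kilobase of gene per million sequenced reads."""
    if ref_len_bp <= 0:
        raise ValueError("ref_len_bp must be positive")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return count / ((ref_len_bp / 1_000) * (total_reads / 1_000_000))


def copies_per_organism(
    codh_rpkm: float,
    marker_rpkms: Sequence[float],
    expected_markers: int = DEFAULT_MARKER_COUNT,
) -> Optional[float]:
    """Gene RPKM over the mean RPKM of the single-copy ribosomal markers.

    Requires exactly ``expected_markers`` values (default 14). Returns None
    (undefined, to be flagged) when the marker mean is zero.
    """
    if len(marker_rpkms) != expected_markers:
        raise ValueError(
            f"expected {expected_markers} marker RPKM values, got {len(marker_rpkms)}"
        )
    mean = sum(marker_rpkms) / len(marker_rpkms)
    if mean == 0:
        return None
    return codh_rpkm / mean


def profile_sample(
    rows: Sequence[AlignmentRow],
    meta: SampleMetadata,
    subject_class: Mapping[str, GeneClass],
    marker_subjects: Sequence[str],
    expected_markers: int = DEFAULT_MARKER_COUNT,
    already_best_hit: bool = False,
) -> AbundanceProfile:
    """Compute the full abundance profile for one sample.

    Gene-class RPKM sums per-subject RPKM over the subjects of the class;
    the marker mean averages the per-marker-protein RPKM over the
    ``marker_subjects`` list (missing markers count as zero, as befits
    single-copy genes simply not observed).
    """
    if not already_best_hit:
        rows = best_hit_per_read(rows)
    retained, _ = filter_read_hits(rows, subject_class)

    counts: dict[str, int] = {}
    for row in retained:
        counts[row.subject_id] = counts.get(row.subject_id, 0) + 1

    subject_rpkm = {
        sid: rpkm(n, subject_class[sid].ref_len_bp, meta.total_reads)
        for sid, n in counts.items()
    }
    class_rpkm: dict[str, float] = {"coxL": 0.0, "cooS": 0.0, "cdhA": 0.0}
    for sid, value in subject_rpkm.items():
        name = subject_class[sid].name
        if name in class_rpkm:
            class_rpkm[name] += value

    marker_rpkms = [subject_rpkm.get(m, 0.0) for m in marker_subjects]
    copies = {
        "Mo": copies_per_organism(class_rpkm["coxL"], marker_rpkms, expected_markers),
        "Ni_cooS": copies_per_organism(class_rpkm["cooS"], marker_rpkms, expected_markers),
        "Ni_cdhA": copies_per_organism(class_rpkm["cdhA"], marker_rpkms, expected_markers),
    }
    if any(v is None for v in copies.values()):
        copies = {k: math.nan if v is None else v for k, v in copies.items()}
    copies["Ni_total"] = copies["Ni_cooS"] + copies["Ni_cdhA"]

    ratio: Optional[float] = None
    ni_total = copies["Ni_total"]
    if not math.isnan(ni_total) and ni_total > 0:
        ratio = copies["Mo"] / ni_total

    return AbundanceProfile(
        sample_id=meta.sample_id,
        rpkm={**class_rpkm, "marker_mean": sum(marker_rpkms) / len(marker_rpkms)},
        copies=copies,
        ratio_mo_ni=ratio,
        depth_m=meta.depth_m,
        o2_uM=meta.o2_uM,
    )


def ratio_profile(profiles: Iterable[AbundanceProfile]) -> pd.DataFrame:
    """Tabulate Mo/Ni ratios against the O2/depth covariates.

    Samples with zero Ni copies carry NaN in ``ratio_mo_ni`` and are flagged
    in ``ratio_defined`` rather than coerced to infinity.
    """
    rows = []
    for p in profiles:
        rows.append({
            "sample_id": p.sample_id,
            "ratio_mo_ni": math.nan if p.ratio_mo_ni is None else p.ratio_mo_ni,
            "ratio_defined": p.ratio_mo_ni is not None,
            "copies_Mo": p.copies.get("Mo", math.nan),
            "copies_Ni_total": p.copies.get("Ni_total", math.nan),
            "depth_m": math.nan if p.depth_m is None else p.depth_m,
            "o2_uM": math.nan if p.o2_uM is None else p.o2_uM,
        })
    return pd.DataFrame(rows)
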