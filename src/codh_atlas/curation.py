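"""Candidate filtering and active-site validation for Ni- and Mo-CODH datasets.

Ni-CODHs (bacterial CooS and archaeal CdhA types) are validated structurally:
the five cysteines that ligate the catalytic Ni-Fe-S C-cluster must all be
present at the positions homologous to the reference, and the accessory B-
and D-cluster regions must not be deleted. A candidate carrying, e.g., a
glutamate where a C-cluster cysteine belongs does not oxidise CO and is
rejected. Mo-CODH large subunits (CoxL) are validated by the Form I
active-site motif (A/S)YRCS(F/L)R; the Form II variant AYRGAGR marks
molybdenum hydroxylases of unresolved CO activity and is rejected.

Upstream of validation, candidates are filtered by raw length (>= 400 aa for
Ni, >= 700 aa for Mo), best homology-search bit score (>= 200), and exact
redundancy (100%-identical sequences collapsed to the first-seen id).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import AlignmentRow, ProteinRecord

LENGTH_THRESHOLDS = {"ni": 400, "mo": 700}
BITSCORE_THRESHOLD = 200.0

# Mo active-site motifs (7-mers, scanned over the whole sequence)
MOTIF_PERMISSIVE = re.compile(r".Y.CS.R")
MOTIF_STRICT = re.compile(r"[AS]YRCS[FL]R")
MOTIF_FORM_II = re.compile(r"AYRGAGR")


@dataclass(frozen=True)
class ReferenceProfile:
    """Reference scaffold locating active-site features in a CODH family.

    Positions and regions are 1-based inclusive indices into
    ``reference.sequence``. ``c_cluster_positions`` are the five C-cluster
    ligand cysteines (Ni only); ``b_cluster_region``/``d_cluster_region``
    bound the accessory Fe-S cluster motifs (Ni only).
    """

    family: str  # "ni" or "mo"
    reference: ProteinRecord
    c_cluster_positions: tuple[int, ...] = ()
    b_cluster_region: Optional[tuple[int, int]] = None
    d_cluster_region: Optional[tuple[int, int]] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("ni", "mo"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "ni":
            if len(self.c_cluster_positions) != 5:
                raise ValueError("Ni profile requires exactly 5 C-cluster positions")
            for pos in self.c_cluster_positions:
                if self.reference.sequence[pos - 1] != "C":
                    raise ValueError(f"reference residue at position {pos} is not cysteine")
            regions = [r for r in (self.b_cluster_region, self.d_cluster_region) if r]
            for lo, hi in regions:
                if not 1 <= lo <= hi <= len(self.reference.sequence):
                    raise ValueError(f"region ({lo},{hi}) outside reference")
            if self.b_cluster_region and self.d_cluster_region:
                b, d = sorted([self.b_cluster_region, self.d_cluster_region])
                if b[1] >= d[0]:
                    raise ValueError("B- and D-cluster regions overlap")


@dataclass(frozen=True)
class CurationVerdict:
    """Pass/fail for one candidate, with machine-readable failure reasons."""

    record_id: str
    family: str
    failed_rules: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.failed_rules


class UnalignableError(ValueError):
    """Candidate could not be anchored to the reference (score below floor)."""


# ---------------------------------------------------------------------------
# Pre-validation filters
# ---------------------------------------------------------------------------

def length_bitscore_filter(
    records: Sequence[ProteinRecord],
    hits: Sequence[AlignmentRow],
    family: str,
) -> list[str]:
    """Ids retained after the raw-length and best-bit-score filters.

    A candidate is retained iff its length is >= the family threshold
    (400 aa Ni, 700 aa Mo) and its best bit score is >= 200; i.e. the
    exclusion rules "length < threshold" and "bit score < 200" are read
    literally, so boundary values survive.
    """
    if family not in LENGTH_THRESHOLDS:
        raise ValueError(f"unknown family {family!r}")
    min_len = LENGTH_THRESHOLDS[family]
    best_bits: dict[str, float] = {}
    for h in hits:
        best_bits[h.query_id] = max(best_bits.get(h.query_id, 0.0), h.bitscore)
    retained = []
    for rec in records:
        if rec.id not in best_bits:
            raise ValueError(f"candidate {rec.id!r} has no homology hit / bit score")
        if len(rec) >= min_len and best_bits[rec.id] >= BITSCORE_THRESHOLD:
            retained.append(rec.id)
    return retained


def dedup_identical(
    records: Sequence[ProteinRecord],
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Collapse 100%-identical sequences; first-seen id wins.

    Returns the unique records (input order preserved) and a map
    ``discarded_id -> kept_id``.
    """
    kept: list[ProteinRecord] = []
    by_seq: dict[str, str] = {}
    dup_map: dict[str, str] = {}
    for rec in records:
        if rec.sequence in by_seq:
            dup_map[rec.id] = by_seq[rec.sequence]
        else:
            by_seq[rec.sequence] = rec.id
            kept.append(rec)
    return kept, dup_map


# ---------------------------------------------------------------------------
# Reference anchoring
# ---------------------------------------------------------------------------

def _make_aligner(open_gap: float = 11.0, extend_gap: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def anchor_to_reference(
    candidate: ProteinRecord,
    profile: ReferenceProfile,
    min_score: float = 0.0,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> dict[int, Optional[int]]:
    """Map each 1-based reference position to its candidate position (or None).

    Uses global pairwise alignment (BLOSUM62, affine gaps open 11 / extend 1).
    The returned map is monotone over non-gap entries. Raises
    :class:`UnalignableError` if the optimal score falls below ``min_score``.
    """
    if aligner is None:
        aligner = _make_aligner()
    alignments = aligner.align(profile.reference.sequence, candidate.sequence)
    if alignments.score < min_score:
        raise UnalignableError(
            f"{candidate.id}: alignment score {alignments.score:.1f} below floor {min_score:.1f}"
        )
    aln = alignments[0]
    pos_map: dict[int, Optional[int]] = {
        i: None for i in range(1, len(profile.reference.sequence) + 1)
    }
    for (rs, re_), (cs, ce) in zip(*aln.aligned):
        for offset in range(re_ - rs):
            pos_map[rs + offset + 1] = cs + offset + 1
    return pos_map


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _region_coverage(
    pos_map: Mapping[int, Optional[int]], region: tuple[int, int]
) -> float:
    lo, hi = region
    total = hi - lo + 1
    covered = sum(1 for p in range(lo, hi + 1) if pos_map.get(p) is not None)
    return covered / total


def validate_ni(
    candidate: ProteinRecord,
    pos_map: Mapping[int, Optional[int]],
    profile: ReferenceProfile,
    coverage_threshold: float = 0.5,
) -> CurationVerdict:
    """Check the five C-cluster ligand cysteines and B/D-cluster presence.

    ``missing_c_cluster_cys``: any of the five mapped positions is gapped or
    is not cysteine in the candidate. ``b_cluster_deleted`` /
    ``d_cluster_deleted``: alignment coverage of the reference region falls
    below ``coverage_threshold`` (default 50%).
    """
    failed: list[str] = []
    for ref_pos in profile.c_cluster_positions:
        cand_pos = pos_map.get(ref_pos)
        if cand_pos is None or candidate.sequence[cand_pos - 1] != "C":
            failed.append("missing_c_cluster_cys")
            break
    if profile.b_cluster_region and _region_coverage(pos_map, profile.b_cluster_region) < coverage_threshold:
        failed.append("b_cluster_deleted")
    if profile.d_cluster_region and _region_coverage(pos_map, profile.d_cluster_region) < coverage_threshold:
        failed.append("d_cluster_deleted")
    return CurationVerdict(record_id=candidate.id, family="ni", failed_rules=tuple(failed))


def validate_mo(candidate: ProteinRecord, strict: bool = False) -> CurationVerdict:
    """Scan for the Form I Mo-CODH active-site motif.

    Permissive mode (default) requires the invariant residues xYxCSxR;
    strict mode requires the full (A/S)YRCS(F/L)R alternation. A sequence
    with the Form II signature AYRGAGR and no Form I match fails as
    ``form_ii``; a sequence with neither fails as ``motif_absent``.
    """
    pattern = MOTIF_STRICT if strict else MOTIF_PERMISSIVE
    if pattern.search(candidate.sequence):
        return CurationVerdict(record_id=candidate.id, family="mo")
    if MOTIF_FORM_II.search(candidate.sequence):
        return CurationVerdict(record_id=candidate.id, family="mo", failed_rules=("form_ii",))
    return CurationVerdict(record_id=candidate.id, family="mo", failed_rules=("motif_absent",))


# ---------------------------------------------------------------------------
# Full curation workflow
# ---------------------------------------------------------------------------

def curate(
    records: Sequence[ProteinRecord],
    hits: Sequence[AlignmentRow],
    profile: ReferenceProfile,
    strict_motif: bool = False,
    coverage_threshold: float = 0.5,
    min_alignment_score: float = 0.0,
) -> list[CurationVerdict]:
    """Run the full curation cascade and return one verdict per input record.

    Order of rules: length/bit-score filter (``too_short`` / ``low_bitscore``),
    exact-duplicate removal (``duplicate``), then family-specific active-site
    validation on the survivors. Verdicts are deterministic and independent
    of dataset order apart from which duplicate id is kept (first seen).
    """
    family = profile.family
    min_len = LENGTH_THRESHOLDS[family]
    best_bits: dict[str, float] = {}
    for h in hits:
        best_bits[h.query_id] = max(best_bits.get(h.query_id, 0.0), h.bitscore)

    verdicts: dict[str, CurationVerdict] = {}
    prefiltered: list[ProteinRecord] = []
    for rec in records:
        failed: list[str] = []
        if len(rec) < min_len:
            failed.append("too_short")
        if best_bits.get(rec.id, 0.0) < BITSCORE_THRESHOLD:
            failed.append("low_bitscore")
        if failed:
            verdicts[rec.id] = CurationVerdict(rec.id, family, tuple(failed))
        else:
            prefiltered.append(rec)

    unique, dup_map = dedup_identical(prefiltered)
    for dup_id in dup_map:
        verdicts[dup_id] = CurationVerdict(dup_id, family, ("duplicate",))

    if family == "mo":
        for rec in unique:
            verdicts[rec.id] = validate_mo(rec, strict=strict_motif)
    else:
        aligner = _make_aligner()
        for rec in unique:
            pos_map = anchor_to_reference(rec, profile, min_score=min_alignment_score, aligner=aligner)
            verdicts[rec.id] = validate_ni(rec, pos_map, profile, coverage_threshold)

    return [verdicts[r.id] for r in records]
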