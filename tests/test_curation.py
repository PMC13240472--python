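"""Curation cascade: length/bit-score filters, dedup, anchoring, validation.

The anchoring oracle re-implements affine-gap global alignment (Gotoh) in
plain numpy, independently of Bio.Align, and checks that ligand-position
mapping agrees between the two implementations on generator sequences.
"""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from codh_atlas import curation as cur
from codh_atlas import synthetic_data as synth
from codh_atlas.io_formats import AlignmentRow, ProteinRecord


def _hit(query, bitscore):
    return AlignmentRow(query_id=query, subject_id="ref", pct_identity=80.0,
                        aln_len=100, mismatches=0, gap_opens=0, qstart=1,
                        qend=100, sstart=1, send=100, evalue=1e-50,
                        bitscore=bitscore)


def _rec(rid, length):
    return ProteinRecord(id=rid, sequence="A" * length)


# ---------------------------------------------------------------------------
# Length / bit-score filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "family,length,bitscore,retained",
    [
        ("ni", 399, 500.0, False),   # below the Ni length threshold
        ("ni", 400, 200.0, True),    # boundary values survive (< is literal)
        ("ni", 450, 199.0, False),   # bit score below 200
        ("mo", 700, 200.0, True),    # Mo boundary
        ("mo", 699, 900.0, False),
    ],
)
def test_length_bitscore_boundaries(family, length, bitscore, retained):
    records = [_rec("x", length)]
    hits = [_hit("x", bitscore)]
    ids = cur.length_bitscore_filter(records, hits, family)
    assert (["x"] if retained else []) == ids


def test_length_filter_requires_a_hit():
    with pytest.raises(ValueError, match="no homology hit"):
        cur.length_bitscore_filter([_rec("x", 500)], [], "ni")


def test_filter_is_monotone_in_thresholds(ni_seqset):
    """Raising any threshold never adds a retained sequence."""
    base = set(cur.length_bitscore_filter(ni_seqset.records, ni_seqset.hits, "ni"))
    stricter = set(cur.length_bitscore_filter(ni_seqset.records, ni_seqset.hits, "mo"))
    assert stricter <= base


# ---------------------------------------------------------------------------
# Dedup
# ---------------------------------------------------------------------------

def test_dedup_identical_keeps_first_seen():
    a = ProteinRecord(id="a", sequence="MKVA")
    b = ProteinRecord(id="b", sequence="MKVA")
    c = ProteinRecord(id="c", sequence="MKVC")
    unique, dup_map = cur.dedup_identical([a, b, c])
    assert [r.id for r in unique] == ["a", "c"]
    assert dup_map == {"b": "a"}


def test_dedup_identity_on_distinct_and_idempotent(ni_seqset):
    unique, dup_map = cur.dedup_identical(ni_seqset.records)
    assert dup_map == {}  # generator sequences are all distinct
    again, again_map = cur.dedup_identical(unique)
    assert again == unique and again_map == {}


# ---------------------------------------------------------------------------
# Anchoring (with an independent Gotoh oracle)
# ---------------------------------------------------------------------------

def test_anchor_reference_to_itself_is_identity(ni_profile):
    pos_map = cur.anchor_to_reference(ni_profile.reference, ni_profile)
    n = len(ni_profile.reference.sequence)
    assert pos_map == {i: i for i in range(1, n + 1)}


def test_anchor_handles_n_terminal_truncation(ni_profile):
    truncated = ProteinRecord(id="t", sequence=ni_profile.reference.sequence[10:])
    pos_map = cur.anchor_to_reference(truncated, ni_profile)
    n = len(ni_profile.reference.sequence)
    assert all(pos_map[i] is None for i in range(1, 11))
    assert all(pos_map[i] == i - 10 for i in range(11, n + 1))


def _gotoh_pairs(ref: str, cand: str, open_gap=11.0, extend=1.0):
    """Independent affine-gap global aligner (Gotoh), plain numpy.

    Returns the aligned (ref_pos, cand_pos) pairs (1-based) of one optimal
    alignment, using the same scoring as the production aligner.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(ref), len(cand)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in cand (ref consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in ref
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_gap - (i - 1) * extend
    for j in range(1, m + 1):
        Y[0, j] = -open_gap - (j - 1) * extend
    for i in range(1, n + 1):
        srow = np.array([blosum[ref[i - 1], c] for c in cand])
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + srow[j - 1]
            X[i, j] = max(M[i - 1, j] - open_gap, X[i - 1, j] - extend)
            Y[i, j] = max(M[i, j - 1] - open_gap, Y[i, j - 1] - extend)
    # traceback
    pairs = []
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    while i > 0 or j > 0:
        if state == 0:
            pairs.append((i, j))
            state = int(np.argmax([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]))
            i, j = i - 1, j - 1
        elif state == 1:
            state = 0 if abs(X[i, j] - (M[i - 1, j] - 11.0)) < 1e-6 else 1
            i -= 1
        else:
            state = 0 if abs(Y[i, j] - (M[i, j - 1] - 11.0)) < 1e-6 else 2
            j -= 1
    return set(reversed(pairs))


def test_anchor_agrees_with_independent_gotoh_at_ligand_columns(ni_seqset):
    """The production aligner and the numpy Gotoh oracle must agree on where
    the five C-cluster ligand positions land, for valid generator sequences."""
    profile = ni_seqset.profile
    valid = ni_seqset.truth[ni_seqset.truth["defect"] == "valid"]["record_id"].head(3)
    by_id = {r.id: r for r in ni_seqset.records}
    for rid in valid:
        rec = by_id[rid]
        pos_map = cur.anchor_to_reference(rec, profile)
        oracle_pairs = _gotoh_pairs(profile.reference.sequence, rec.sequence)
        for ref_pos in profile.c_cluster_positions:
            cand_pos = pos_map[ref_pos]
            assert cand_pos is not None
            assert (ref_pos, cand_pos) in oracle_pairs
            assert rec.sequence[cand_pos - 1] == "C"


# ---------------------------------------------------------------------------
# Ni validation
# ---------------------------------------------------------------------------

def test_validate_ni_reference_passes(ni_profile):
    pos_map = cur.anchor_to_reference(ni_profile.reference, ni_profile)
    verdict = cur.validate_ni(ni_profile.reference, pos_map, ni_profile)
    assert verdict.passed


def test_validate_ni_glutamate_at_ligand_position_fails(ni_profile):
    seq = list(ni_profile.reference.sequence)
    seq[ni_profile.c_cluster_positions[2] - 1] = "E"
    mutant = ProteinRecord(id="m", sequence="".join(seq))
    pos_map = cur.anchor_to_reference(mutant, ni_profile)
    verdict = cur.validate_ni(mutant, pos_map, ni_profile)
    assert verdict.failed_rules == ("missing_c_cluster_cys",)


def test_validate_ni_planted_d_deletion_fails(ni_seqset):
    truth = ni_seqset.truth.set_index("record_id")
    by_id = {r.id: r for r in ni_seqset.records}
    d_del = truth[truth["defect"] == "d_del"].index
    assert len(d_del) > 0
    for rid in d_del:
        rec = by_id[rid]
        pos_map = cur.anchor_to_reference(rec, ni_seqset.profile)
        verdict = cur.validate_ni(rec, pos_map, ni_seqset.profile)
        assert verdict.failed_rules == ("d_cluster_deleted",)


# ---------------------------------------------------------------------------
# Mo validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "motif,strict,expected_rules",
    [
        ("AYRCSFR", False, ()),          # canonical Form I
        ("AYRCSFR", True, ()),
        ("SYRCSLR", True, ()),           # allowed alternation under strict
        ("TYRCSAR", False, ()),          # permissive tolerates substitutions
        ("TYRCSAR", True, ("motif_absent",)),
        ("AYRGAGR", False, ("form_ii",)),
        ("AYRGAGR", True, ("form_ii",)),
        ("AAAAAAA", False, ("motif_absent",)),
    ],
)
def test_validate_mo_motif_modes(motif, strict, expected_rules):
    seq = "MGHKL" * 10 + motif + "LKHGM" * 10
    rec = ProteinRecord(id="m", sequence=seq)
    verdict = cur.validate_mo(rec, strict=strict)
    assert verdict.failed_rules == expected_rules


def test_validate_mo_form_i_wins_over_form_ii():
    # a sequence carrying both motifs is Form I (the diagnostic motif is present)
    rec = ProteinRecord(id="m", sequence="G" * 10 + "AYRCSFR" + "G" * 10 + "AYRGAGR")
    assert cur.validate_mo(rec).passed


# ---------------------------------------------------------------------------
# Whole-cascade determinism
# ---------------------------------------------------------------------------

def test_curate_is_order_independent(mo_seqset):
    verdicts = {v.record_id: v for v in
                cur.curate(mo_seqset.records, mo_seqset.hits, mo_seqset.profile)}
    reversed_verdicts = {v.record_id: v for v in
                         cur.curate(list(reversed(mo_seqset.records)),
                                    mo_seqset.hits, mo_seqset.profile)}
    assert verdicts == reversed_verdicts
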