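"""Synthetic pipeline inputs with planted ground truth.

Every stage of the pipeline (curation, D-cluster typing, genome-context
classification, operon detection, abundance profiling) can be exercised on
data built here, with a truth table recording exactly what was planted so
tests can demand exact recovery. A fixed seed fully determines every output.

The sequence generator mutates a synthetic reference scaffold: valid
candidates keep all active-site features; each defective candidate carries
exactly one planted defect (C-cluster Cys->Glu, B- or D-region deletion,
Form II motif, missing motif, or short length). Point substitutions and
indels away from the critical regions force non-trivial alignments.

The metagenome generator draws per-gene read counts from a Poisson model:
``count ~ Poisson(kappa * L_kb * total_M * marker_rpkm)`` where ``kappa`` is
the planted average gene copies per organism, single-copy ribosomal markers
have kappa = 1, and ``marker_rpkm`` sets the community sequencing scale.
Per-read percent identities are drawn from a normal around the planted
class identity (sd 3 points) so the identity filters bite measurably; a
small planted fraction of low-identity (~45%) reads must be removed by the
50%/60% gates, and decoy reads hit a subject outside every gene class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .curation import ReferenceProfile
from .io_formats import AlignmentRow, CdsRecord, HmmHitRow, ProteinRecord, SampleMetadata

# Background alphabet excludes cysteine so that every cysteine in a generated
# sequence is a planted one (windows and motifs stay unambiguous).
_BACKGROUND = "ADEFGHIKLMNPQRSTVWY"

NI_LENGTH = 560
MO_LENGTH = 780
NI_D_REGION = (30, 52)
NI_B_REGION = (60, 108)
NI_B_CYS = (65, 68, 71, 95)
NI_C_POSITIONS = (130, 211, 295, 333, 446)
NI_REF_D_CYS = (38, 42)  # the reference scaffold's own type-I D-cluster pair
MO_MOTIF_START = 380  # 1-based start of the 7-mer active-site motif

_PROFILE_SEED = 97_241  # fixed: reference scaffolds are constants, not draws

DEFAULT_NI_DEFECT_MIX = {
    "valid": 0.55, "c_cys_mut": 0.15, "b_del": 0.10, "d_del": 0.10, "short": 0.10,
}
DEFAULT_MO_DEFECT_MIX = {
    "valid": 0.60, "form_ii": 0.20, "motif_absent": 0.10, "short": 0.10,
}
DEFAULT_DTYPE_MIX = {"I": 0.30, "II": 0.25, "III": 0.25, "IV": 0.10, "V": 0.10}

EXPECTED_RULE = {
    "valid": "",
    "c_cys_mut": "missing_c_cluster_cys",
    "b_del": "b_cluster_deleted",
    "d_del": "d_cluster_deleted",
    "short": "too_short",
    "form_ii": "form_ii",
    "motif_absent": "motif_absent",
}


def _counts_from_mix(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Deterministic largest-remainder apportionment of n items to classes."""
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("mix proportions must sum to 1")
    raw = {k: n * p for k, p in mix.items()}
    counts = {k: int(v) for k, v in raw.items()}
    remainder = n - sum(counts.values())
    order = sorted(mix, key=lambda k: (counts[k] - raw[k], k))
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def _background_seq(rng: np.random.Generator, length: int) -> list[str]:
    return [_BACKGROUND[i] for i in rng.integers(0, len(_BACKGROUND), size=length)]


def make_reference_profile(family: str) -> ReferenceProfile:
    """Deterministic synthetic reference scaffold for a CODH family.

    The Ni scaffold carries the five C-cluster ligand cysteines, a B-cluster
    cysteine block and a type-I D-cluster pair; the Mo scaffold carries the
    AYRCSFR Form I motif. Positions are fixed constants independent of any
    user seed.
    """
    rng = np.random.default_rng(_PROFILE_SEED if family == "ni" else _PROFILE_SEED + 1)
    if family == "ni":
        seq = _background_seq(rng, NI_LENGTH)
        for pos in NI_C_POSITIONS:
            seq[pos - 1] = "C"
        for pos in NI_B_CYS:
            seq[pos - 1] = "C"
        # reference D-cluster: type I pair (Cys-x3-Cys) inside the D region
        for pos in NI_REF_D_CYS:
            seq[pos - 1] = "C"
        record = ProteinRecord(id="ni_ref_synthetic", sequence="".join(seq),
                               description="synthetic Ni-CODH reference scaffold")
        return ReferenceProfile(
            family="ni",
            reference=record,
            c_cluster_positions=NI_C_POSITIONS,
            b_cluster_region=NI_B_REGION,
            d_cluster_region=NI_D_REGION,
            notes="synthetic scaffold; ligand positions are planted, not structural",
        )
    if family == "mo":
        seq = _background_seq(rng, MO_LENGTH)
        seq[MO_MOTIF_START - 1:MO_MOTIF_START + 6] = list("AYRCSFR")
        record = ProteinRecord(id="mo_ref_synthetic", sequence="".join(seq),
                               description="synthetic Mo-CODH (CoxL) reference scaffold")
        return ReferenceProfile(family="mo", reference=record,
                                notes="synthetic scaffold with planted Form I motif")
    raise ValueError(f"unknown family {family!r}")


class _TrackedSeq:
    """A mutable sequence that tracks original reference coordinates.

    Substitution keeps tags; insertions carry tag None; deletions drop tags.
    ``final_position(ref_pos)`` returns the 1-based position in the edited
    sequence, or None if that residue was deleted.
    """

    def __init__(self, sequence: str):
        self.chars = list(sequence)
        self.tags: list[Optional[int]] = list(range(1, len(sequence) + 1))

    def substitute(self, ref_pos: int, aa: str) -> None:
        idx = self.tags.index(ref_pos)
        self.chars[idx] = aa

    def delete_ref_range(self, lo: int, hi: int) -> None:
        keep = [(c, t) for c, t in zip(self.chars, self.tags) if t is None or not lo <= t <= hi]
        self.chars = [c for c, _ in keep]
        self.tags = [t for _, t in keep]

    def insert_after_ref(self, ref_pos: int, fragment: str) -> None:
        idx = self.tags.index(ref_pos) + 1
        self.chars[idx:idx] = list(fragment)
        self.tags[idx:idx] = [None] * len(fragment)

    def truncate(self, length: int) -> None:
        self.chars = self.chars[:length]
        self.tags = self.tags[:length]

    def final_position(self, ref_pos: int) -> Optional[int]:
        try:
            return self.tags.index(ref_pos) + 1
        except ValueError:
            return None

    def __str__(self) -> str:
        return "".join(self.chars)


def _plant_dtype(
    seq: _TrackedSeq, rng: np.random.Generator, dtype: str
) -> list[int]:
    """Rewrite the D-region cysteine content to realise a D-cluster type.

    Returns the reference positions of the planted cysteines.
    """
    lo, hi = NI_D_REGION
    # clear only the reference's own D-cluster cysteines; leaving the rest of
    # the region untouched keeps alignment coverage high for valid candidates
    for p in NI_REF_D_CYS:
        seq.substitute(p, _BACKGROUND[rng.integers(0, len(_BACKGROUND))])
    if dtype == "V":
        return []
    if dtype == "IV":
        p = int(rng.integers(lo, hi + 1))
        seq.substitute(p, "C")
        return [p]
    spacing = {"I": 3, "III": 2}.get(dtype)
    if spacing is None:  # type II
        spacing = int(rng.integers(7, 17))
    p1 = int(rng.integers(lo, hi - spacing))  # p2 = p1 + spacing + 1 <= hi
    p2 = p1 + spacing + 1
    seq.substitute(p1, "C")
    seq.substitute(p2, "C")
    return [p1, p2]


@dataclass
class SequenceSet:
    """Output bundle of :func:`make_codh_sequences`."""

    records: list[ProteinRecord]
    hits: list[AlignmentRow]
    truth: pd.DataFrame
    profile: ReferenceProfile


def make_codh_sequences(
    n: int,
    family: str,
    defect_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    dtype_mix: Optional[dict[str, float]] = None,
    substitution_rate: float = 0.03,
) -> SequenceSet:
    """Generate candidate CODH sequences with planted curation outcomes.

    Each record carries exactly the defect its truth row states; valid
    records pass every curation rule. Ni records additionally carry a
    planted D-cluster type. A homology-hit row with a passing bit score is
    emitted per record so the curation cascade can run end to end.
    """
    profile = make_reference_profile(family)
    rng = np.random.default_rng(seed)
    mix = defect_mix or (DEFAULT_NI_DEFECT_MIX if family == "ni" else DEFAULT_MO_DEFECT_MIX)
    known = set(DEFAULT_NI_DEFECT_MIX if family == "ni" else DEFAULT_MO_DEFECT_MIX)
    if set(mix) - known:
        raise ValueError(f"unknown defect classes {set(mix) - known}")
    counts = _counts_from_mix(n, mix)
    defects = [d for d, c in sorted(counts.items()) for _ in range(c)]
    rng.shuffle(defects)

    dmix = dtype_mix or DEFAULT_DTYPE_MIX
    dtype_counts = _counts_from_mix(n, dmix) if family == "ni" else {}
    dtypes = [t for t, c in sorted(dtype_counts.items()) for _ in range(c)]
    rng.shuffle(dtypes)

    ref_len = len(profile.reference.sequence)
    if family == "ni":
        critical = set(NI_C_POSITIONS)
        critical |= set(range(NI_D_REGION[0] - 8, NI_D_REGION[1] + 9))
        critical |= set(range(NI_B_REGION[0], NI_B_REGION[1] + 1))
        safe_zone = (460, 540)
        short_len = 360
    else:
        critical = set(range(MO_MOTIF_START - 2, MO_MOTIF_START + 9))
        safe_zone = (560, 740)
        short_len = 650

    records, hits, rows = [], [], []
    for i in range(n):
        rec_id = f"{family}_{i:05d}"
        defect = defects[i]
        seq = _TrackedSeq(profile.reference.sequence)

        planted_cys_ref: list[int] = []
        dtype = ""
        if family == "ni":
            dtype = dtypes[i]
            planted_cys_ref = _plant_dtype(seq, rng, dtype)

        # background substitutions away from critical positions
        n_sub = rng.binomial(ref_len, substitution_rate)
        for pos in rng.choice(ref_len, size=n_sub, replace=False) + 1:
            if int(pos) in critical:
                continue
            cur = seq.chars[seq.tags.index(int(pos))]
            choices = [a for a in _BACKGROUND if a != cur]
            seq.substitute(int(pos), choices[rng.integers(0, len(choices))])

        # planted defect
        if defect == "c_cys_mut":
            target = NI_C_POSITIONS[rng.integers(0, len(NI_C_POSITIONS))]
            seq.substitute(int(target), "E")
        elif defect == "form_ii":
            for off, aa in enumerate("AYRGAGR"):
                seq.substitute(MO_MOTIF_START + off, aa)
        elif defect == "motif_absent":
            for off in range(7):
                seq.substitute(MO_MOTIF_START + off,
                               _BACKGROUND[rng.integers(0, len(_BACKGROUND))])

        # indels in the safe zone (after every critical feature) so the
        # candidate does not align to the reference trivially
        ins_at = int(rng.integers(safe_zone[0], safe_zone[1] - 20))
        frag = "".join(_background_seq(rng, int(rng.integers(3, 9))))
        seq.insert_after_ref(ins_at, frag)
        del_at = int(rng.integers(ins_at + 10, safe_zone[1]))
        seq.delete_ref_range(del_at, del_at + int(rng.integers(1, 4)))

        if defect == "b_del":
            seq.delete_ref_range(*NI_B_REGION)
        elif defect == "d_del":
            seq.delete_ref_range(*NI_D_REGION)
        elif defect == "short":
            seq.truncate(short_len)

        cand_cys = [seq.final_position(p) for p in planted_cys_ref]
        d_lo = seq.final_position(NI_D_REGION[0]) if family == "ni" else None
        d_hi = seq.final_position(NI_D_REGION[1]) if family == "ni" else None

        record = ProteinRecord(id=rec_id, sequence=str(seq), source_db="synthetic")
        records.append(record)
        bitscore = float(rng.uniform(300, 900))
        hits.append(AlignmentRow(
            query_id=rec_id, subject_id=profile.reference.id,
            pct_identity=round(float(rng.uniform(60, 95)), 1),
            aln_len=len(record), mismatches=0, gap_opens=0,
            qstart=1, qend=len(record), sstart=1, send=ref_len,
            evalue=1e-100, bitscore=round(bitscore, 1),
        ))
        rows.append({
            "record_id": rec_id,
            "family": family,
            "defect": defect,
            "expected_rule": EXPECTED_RULE[defect],
            "dtype": dtype if (family == "ni" and defect not in ("d_del", "short")) else "",
            "d_window_start": d_lo if defect != "d_del" else None,
            "d_window_end": d_hi if defect != "d_del" else None,
            "planted_cys": ";".join(str(c) for c in cand_cys if c is not None),
        })

    return SequenceSet(records=records, hits=hits,
                       truth=pd.DataFrame(rows), profile=profile)


# ---------------------------------------------------------------------------
# Genome-context tables
# ---------------------------------------------------------------------------

# (product text, COG id) per trigger gene; one entry per functional group.
_NI_TRIGGER_GENES = {
    "WLP": [("acetyl-CoA synthase beta subunit", "COG1614")],
    "incomplete_acs_cluster": [
        ("acetyl-CoA decarbonylase/synthase complex subunit cdhB", "COG2069"),
        ("acetyl-CoA decarbonylase/synthase complex subunit cdhD", "COG1152"),
        ("acetyl-CoA decarbonylase/synthase complex subunit cdhE", "COG1456"),
    ],
    "one_carbon_pool": [
        ("formate dehydrogenase alpha subunit", "COG0243"),
        ("methylene-tetrahydrofolate dehydrogenase folD", "COG0190"),
        ("methylene-tetrahydrofolate reductase metF", "COG0685"),
    ],
    "ECH": [("energy-converting hydrogenase subunit echE", "COG3261")],
    "F420_hydrogenase": [("F420-reducing hydrogenase subunit frhA", "COG3259")],
    "FNOR": [("FAD-NAD(P) oxidoreductase", "COG1251")],
    "CooF": [("ferredoxin-like protein CooF", "COG0437")],
    "heterodisulfide_reductase": [("heterodisulfide reductase subunit hdrA", "COG2048")],
    "NADH_ubiquinone": [("NADH:ubiquinone oxidoreductase subunit nuoF", "COG0649")],
    "CooC": [("CODH maturation nickel chaperone CooC", "COG3640")],
    "CooA": [("CO-sensing transcriptional regulator CooA", None)],
    "ABC_transporter": [("ABC transporter ATP-binding protein", "COG1131")],
    "glycine_cleavage": [("glycine cleavage system protein gcvP", "COG0403")],
    "hybrid/other": [("hybrid cluster protein hcp", "COG1151")],
}

DEFAULT_NI_GROUP_MIX = {
    "WLP": 0.28, "WLP_distant": 0.08, "incomplete_acs_cluster": 0.05,
    "one_carbon_pool": 0.08, "ECH": 0.06, "F420_hydrogenase": 0.03,
    "FNOR": 0.05, "CooF": 0.04, "heterodisulfide_reductase": 0.02,
    "NADH_ubiquinone": 0.02, "CooC": 0.02, "CooA": 0.01,
    "ABC_transporter": 0.03, "glycine_cleavage": 0.02, "hybrid/other": 0.01,
    "standalone": 0.20,
}

DEFAULT_COX_STRUCTURE_MIX = {
    "MSL_complete": 0.90, "SL_partial": 0.05, "L_only": 0.03, "other_order": 0.02,
}
DEFAULT_COXG_MIX = {"proximal": 0.66, "distant": 0.27, "absent": 0.07}

_FILLER_PRODUCTS = [
    "hypothetical protein", "DUF domain-containing protein",
    "MFS permease", "elongation factor Tu", "DNA polymerase III subunit",
    "ribosomal protein L2", "tRNA ligase", "cell division protein FtsZ",
]

_CLADES = ("A", "B", "C", "D", "E", "F", "G")


@dataclass
class ContextSet:
    """Output bundle of :func:`make_context_tables`."""

    cds: list[CdsRecord]
    rps_hits: list[AlignmentRow]
    hmm_hits: list[HmmHitRow]
    truth: pd.DataFrame


def _filler_cds(rng: np.random.Generator, genome: str, contig: str, idx: int,
                pid: str) -> CdsRecord:
    start = (idx - 1) * 1200 + 1
    return CdsRecord(
        genome_id=genome, contig_id=contig, cds_index=idx,
        start=start, end=start + 899,
        strand="+" if rng.random() < 0.5 else "-",
        product=_FILLER_PRODUCTS[rng.integers(0, len(_FILLER_PRODUCTS))],
        cog_id=None, protein_id=pid,
    )


def make_context_tables(
    n_genomes: int,
    group_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    window: int = 15,
    multicopy_fraction: float = 0.2,
) -> ContextSet:
    """Generate Ni-CODH genome neighbourhoods realising planted groups.

    Each genome gets one contig of ~33 CDS with a focal cooS/cdhA gene and,
    for non-standalone groups, a trigger CDS inside the +/-15 window. Half
    the triggers are recognisable only through their COG (assigned via an
    RPS hit below the e < 1e-6 gate is a decoy; the real one is at 1e-9),
    the other half only through their product text. "WLP_distant" genomes
    carry proximal cdhB/D/E plus a genome-level acsB/cdhA HMM hit passing
    the E <= 1e-30 / 350-762 aa gate; "incomplete_acs_cluster" genomes carry
    the same neighbourhood with only gate-violating hits. A planted fraction
    of genomes carries a second CODH copy (for multicopy statistics), each
    copy with a clade label.
    """
    rng = np.random.default_rng(seed)
    mix = group_mix or DEFAULT_NI_GROUP_MIX
    counts = _counts_from_mix(n_genomes, mix)
    groups = [g for g, c in sorted(counts.items()) for _ in range(c)]
    rng.shuffle(groups)

    cds_rows: list[CdsRecord] = []
    rps: list[AlignmentRow] = []
    hmm: list[HmmHitRow] = []
    truth_rows = []

    for g_idx in range(n_genomes):
        genome = f"G{g_idx:04d}"
        contig = "ctg1"
        planted = groups[g_idx]
        expected = "WLP" if planted == "WLP_distant" else planted
        n_cds = int(rng.integers(31, 36))
        focal_idx = int(rng.integers(window + 1, n_cds - window + 1))
        pid = lambda idx: f"{genome}|p{idx:03d}"

        genome_cds: dict[int, CdsRecord] = {}
        for idx in range(1, n_cds + 1):
            genome_cds[idx] = _filler_cds(rng, genome, contig, idx, pid(idx))

        focal_clade = "A" if planted in ("WLP_distant", "incomplete_acs_cluster") else \
            _CLADES[rng.integers(0, len(_CLADES))]
        focal_product = ("acetyl-CoA decarbonylase/synthase complex alpha subunit cdhA"
                         if focal_clade == "A" else "carbon monoxide dehydrogenase CooS")
        start = (focal_idx - 1) * 1200 + 1
        genome_cds[focal_idx] = CdsRecord(
            genome_id=genome, contig_id=contig, cds_index=focal_idx,
            start=start, end=start + 1913, strand="+",
            product=focal_product, cog_id=None, protein_id=pid(focal_idx),
        )

        def place_trigger(product: str, cog: Optional[str], via_cog: bool) -> str:
            offsets = [o for o in range(-window, window + 1)
                       if o != 0 and 1 <= focal_idx + o <= n_cds]
            idx = focal_idx + offsets[rng.integers(0, len(offsets))]
            s = (idx - 1) * 1200 + 1
            shown_product = "hypothetical protein" if via_cog else product
            genome_cds[idx] = CdsRecord(
                genome_id=genome, contig_id=contig, cds_index=idx,
                start=s, end=s + 899, strand="+",
                product=shown_product, cog_id=None, protein_id=pid(idx),
            )
            if via_cog and cog is not None:
                rps.append(AlignmentRow(
                    query_id=pid(idx), subject_id=cog, pct_identity=45.0,
                    aln_len=250, mismatches=100, gap_opens=3, qstart=1, qend=250,
                    sstart=1, send=250, evalue=1e-9, bitscore=180.0,
                ))
                # decoy hit above the RPS gate: must never be assigned
                rps.append(AlignmentRow(
                    query_id=pid(idx), subject_id="COG9999", pct_identity=30.0,
                    aln_len=80, mismatches=50, gap_opens=2, qstart=1, qend=80,
                    sstart=1, send=80, evalue=1e-4, bitscore=40.0,
                ))
            return pid(idx)

        distant = None
        if planted in ("WLP_distant", "incomplete_acs_cluster"):
            genes = _NI_TRIGGER_GENES["incomplete_acs_cluster"]
            product, cog = genes[rng.integers(0, len(genes))]
            via_cog = bool(rng.random() < 0.5)
            place_trigger(product, cog, via_cog)
            if planted == "WLP_distant":
                hmm.append(HmmHitRow(target_id=f"{genome}|distant_acsB",
                                     profile_id="COG1614", evalue=1e-35, target_len=600))
                distant = "acsB_cdhA_distant"
            else:
                # gate-violating hits: weak e-value, and out-of-window length
                hmm.append(HmmHitRow(target_id=f"{genome}|weak_acsB",
                                     profile_id="COG1614", evalue=1e-29, target_len=600))
                hmm.append(HmmHitRow(target_id=f"{genome}|short_acsB",
                                     profile_id="COG1614", evalue=1e-40, target_len=349))
        elif planted != "standalone":
            genes = _NI_TRIGGER_GENES[planted]
            product, cog = genes[rng.integers(0, len(genes))]
            via_cog = bool(rng.random() < 0.5) and cog is not None
            place_trigger(product, cog, via_cog)

        cds_rows.extend(genome_cds[idx] for idx in sorted(genome_cds))
        truth_rows.append({
            "genome_id": genome, "focal_protein_id": pid(focal_idx),
            "focal_cds_index": focal_idx, "planted": planted,
            "expected_group": expected, "distant_partner": distant or "",
            "clade": focal_clade, "n_codh": 1,
        })

        # second CODH copy (standalone context) for multicopy statistics
        if rng.random() < multicopy_fraction:
            contig2 = "ctg2"
            n2 = int(rng.integers(5, 12))
            focal2 = int(rng.integers(1, n2 + 1))
            extra_clade = _CLADES[rng.integers(0, len(_CLADES))]
            for idx in range(1, n2 + 1):
                p2 = f"{genome}|q{idx:03d}"
                if idx == focal2:
                    s = (idx - 1) * 1200 + 1
                    cds_rows.append(CdsRecord(
                        genome_id=genome, contig_id=contig2, cds_index=idx,
                        start=s, end=s + 1913, strand="+",
                        product="carbon monoxide dehydrogenase CooS",
                        cog_id=None, protein_id=p2,
                    ))
                else:
                    cds_rows.append(_filler_cds(rng, genome, contig2, idx, p2))
            truth_rows[-1]["n_codh"] = 2
            truth_rows[-1]["clade2"] = extra_clade

    truth = pd.DataFrame(truth_rows)
    if "clade2" not in truth.columns:
        truth["clade2"] = np.nan
    return ContextSet(cds=cds_rows, rps_hits=rps, hmm_hits=hmm, truth=truth)


def make_cox_context_tables(
    n_genomes: int,
    structure_mix: Optional[dict[str, float]] = None,
    coxg_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    window: int = 15,
) -> ContextSet:
    """Generate Mo-CODH (coxL) neighbourhoods with planted operon structures.

    MSL_complete genomes carry coxM-coxS-coxL consecutively on one strand in
    transcriptional order (half on the minus strand, where genomic order
    reverses); other_order genomes carry all three genes shuffled; coxG is
    planted proximal, distant (qualifying HMM hit) or absent, with
    gate-violating decoy hits planted for absent genomes.
    """
    rng = np.random.default_rng(seed)
    smix = structure_mix or DEFAULT_COX_STRUCTURE_MIX
    gmix = coxg_mix or DEFAULT_COXG_MIX
    structures = [s for s, c in sorted(_counts_from_mix(n_genomes, smix).items())
                  for _ in range(c)]
    coxg_states = [s for s, c in sorted(_counts_from_mix(n_genomes, gmix).items())
                   for _ in range(c)]
    rng.shuffle(structures)
    rng.shuffle(coxg_states)

    cds_rows: list[CdsRecord] = []
    hmm: list[HmmHitRow] = []
    truth_rows = []

    def cox_cds(genome: str, contig: str, idx: int, strand: str, role: str,
                pid: str) -> CdsRecord:
        names = {"coxM": "aerobic CO dehydrogenase medium subunit coxM",
                 "coxS": "aerobic CO dehydrogenase small subunit coxS",
                 "coxL": "aerobic CO dehydrogenase large subunit coxL",
                 "coxG": "CO dehydrogenase accessory protein coxG"}
        s = (idx - 1) * 1200 + 1
        return CdsRecord(genome_id=genome, contig_id=contig, cds_index=idx,
                         start=s, end=s + 899, strand=strand,
                         product=names[role], cog_id=None, protein_id=pid)

    for g_idx in range(n_genomes):
        genome = f"M{g_idx:04d}"
        contig = "ctg1"
        structure = structures[g_idx]
        coxg = coxg_states[g_idx]
        n_cds = int(rng.integers(31, 36))
        focal_idx = int(rng.integers(window + 1, n_cds - window + 1))
        pid = lambda idx: f"{genome}|p{idx:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        step = 1 if strand == "+" else -1

        genome_cds: dict[int, CdsRecord] = {
            idx: _filler_cds(rng, genome, contig, idx, pid(idx))
            for idx in range(1, n_cds + 1)
        }
        genome_cds[focal_idx] = cox_cds(genome, contig, focal_idx, strand, "coxL", pid(focal_idx))

        if structure == "MSL_complete":
            genome_cds[focal_idx - step] = cox_cds(genome, contig, focal_idx - step, strand, "coxS", pid(focal_idx - step))
            genome_cds[focal_idx - 2 * step] = cox_cds(genome, contig, focal_idx - 2 * step, strand, "coxM", pid(focal_idx - 2 * step))
        elif structure == "SL_partial":
            genome_cds[focal_idx - step] = cox_cds(genome, contig, focal_idx - step, strand, "coxS", pid(focal_idx - step))
        elif structure == "other_order":
            # all three present but S and M swapped: M directly upstream, S beyond
            genome_cds[focal_idx - step] = cox_cds(genome, contig, focal_idx - step, strand, "coxM", pid(focal_idx - step))
            genome_cds[focal_idx - 2 * step] = cox_cds(genome, contig, focal_idx - 2 * step, strand, "coxS", pid(focal_idx - 2 * step))

        if coxg == "proximal":
            offsets = [o for o in range(-window, window + 1)
                       if abs(o) >= 4 and 1 <= focal_idx + o <= n_cds]
            idx = focal_idx + offsets[rng.integers(0, len(offsets))]
            genome_cds[idx] = cox_cds(genome, contig, idx,
                                      "+" if rng.random() < 0.5 else "-", "coxG", pid(idx))
        elif coxg == "distant":
            hmm.append(HmmHitRow(target_id=f"{genome}|distant_coxG",
                                 profile_id="COG3427", evalue=1e-35, target_len=300))
        else:
            hmm.append(HmmHitRow(target_id=f"{genome}|weak_coxG",
                                 profile_id="COG3427", evalue=1e-29, target_len=300))
            hmm.append(HmmHitRow(target_id=f"{genome}|long_coxG",
                                 profile_id="COG3427", evalue=1e-40, target_len=451))

        cds_rows.extend(genome_cds[idx] for idx in sorted(genome_cds))
        truth_rows.append({
            "genome_id": genome, "focal_protein_id": pid(focal_idx),
            "focal_cds_index": focal_idx, "strand": strand,
            "expected_structure": structure, "expected_coxg": coxg,
        })

    return ContextSet(cds=cds_rows, rps_hits=[], hmm_hits=hmm,
                      truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# Metagenome simulation
# ---------------------------------------------------------------------------

REFERENCE_GENES = {
    # subject id -> (gene class name, protein length aa)
    "coxL_ref": ("coxL", 780),
    "cooS_ref": ("cooS", 560),
    "cdhA_ref": ("cdhA", 560),
}
MARKER_SUBJECTS = tuple(f"marker_{i:02d}" for i in range(1, 15))
MARKER_LEN_AA = 150
PLANTED_IDENTITY = {"coxL": 75.0, "cooS": 70.0, "cdhA": 70.0, "ribosomal_marker": 80.0}


def reference_gene_classes() -> dict[str, "object"]:
    """Subject -> GeneClass map for the synthetic reference database
    (nucleotide length = 3 x protein length)."""
    from .abundance import DEFAULT_MIN_IDENTITY, GeneClass

    classes: dict[str, GeneClass] = {}
    for sid, (name, aa) in REFERENCE_GENES.items():
        classes[sid] = GeneClass(name=name, ref_len_bp=3 * aa,
                                 min_identity=DEFAULT_MIN_IDENTITY[name])
    for sid in MARKER_SUBJECTS:
        classes[sid] = GeneClass(name="ribosomal_marker", ref_len_bp=3 * MARKER_LEN_AA,
                                 min_identity=DEFAULT_MIN_IDENTITY["ribosomal_marker"])
    return classes


@dataclass(frozen=True)
class SampleSpec:
    """Planted study conditions for one metagenomic sample."""

    sample_id: str
    total_reads: int
    kappa: dict[str, float]  # gene copies per organism for coxL/cooS/cdhA
    depth_m: Optional[float] = None
    o2_uM: Optional[float] = None
    habitat: str = "synthetic water column"

    @property
    def expected_ratio(self) -> Optional[float]:
        ni = self.kappa.get("cooS", 0.0) + self.kappa.get("cdhA", 0.0)
        return None if ni == 0 else self.kappa.get("coxL", 0.0) / ni


def default_o2_gradient_samples(total_reads: int = 1_000_000) -> list[SampleSpec]:
    """Six water-column samples along a declining oxygen gradient.

    Planted so Mo-CODH copies stay roughly flat while Ni-CODH copies rise
    steeply as O2 falls, giving a Mo/Ni ratio that spans roughly three
    orders of magnitude from the oxygenated surface to anoxic depth —
    the qualitative condition a stratified, seasonally anoxic water column
    imposes.
    """
    specs = []
    o2 = [250.0, 150.0, 80.0, 30.0, 10.0, 0.5]
    depth = [10.0, 50.0, 100.0, 130.0, 170.0, 200.0]
    kappa_ni = [1e-4, 4e-4, 2e-3, 8e-3, 3e-2, 8e-2]
    kappa_mo = [0.05, 0.05, 0.045, 0.04, 0.04, 0.035]
    for i in range(6):
        specs.append(SampleSpec(
            sample_id=f"wc_{i:02d}", total_reads=total_reads,
            kappa={"coxL": kappa_mo[i], "cooS": kappa_ni[i] * 0.8, "cdhA": kappa_ni[i] * 0.2},
            depth_m=depth[i], o2_uM=o2[i],
        ))
    return specs


def default_sediment_samples(total_reads: int = 1_000_000) -> list[SampleSpec]:
    """Subsurface-sediment profile planting a cooS -> cdhA dominance switch.

    The archaeal (cdhA) share of Ni-CODH rises with sediment depth and
    crosses the bacterial (cooS) share at ~50 cm, emulating archaeal
    enrichment in cold-seep sediments. Depths are in metres of sediment.
    """
    specs = []
    depth_cm = [5.0, 20.0, 40.0, 60.0, 100.0, 200.0]
    archaeal_frac = [0.05, 0.15, 0.35, 0.65, 0.85, 0.95]
    for i, (d, f) in enumerate(zip(depth_cm, archaeal_frac)):
        ni = 0.08
        specs.append(SampleSpec(
            sample_id=f"sed_{i:02d}", total_reads=total_reads,
            kappa={"coxL": 0.01, "cooS": ni * (1 - f), "cdhA": ni * f},
            depth_m=d / 100.0, o2_uM=None, habitat="synthetic subsurface sediment",
        ))
    return specs


@dataclass
class MetagenomeSet:
    """Output bundle of :func:`make_metagenome`."""

    hits: dict[str, list[AlignmentRow]]
    metadata: list[SampleMetadata]
    truth: pd.DataFrame
    subject_class: dict[str, "object"]
    marker_subjects: tuple[str, ...]


def make_metagenome(
    samples: Sequence[SampleSpec],
    seed: int = 0,
    marker_rpkm: float = 1000.0,
    identity_sd: float = 3.0,
    low_identity_fraction: float = 0.02,
    decoy_fraction: float = 0.01,
) -> MetagenomeSet:
    """Simulate per-sample read-hit tables under the Poisson copy model."""
    rng = np.random.default_rng(seed)
    classes = reference_gene_classes()
    hits: dict[str, list[AlignmentRow]] = {}
    truth_rows = []

    for spec in samples:
        rows: list[AlignmentRow] = []
        read_no = 0

        def emit(subject: str, count: int, identity_mean: float) -> None:
            nonlocal read_no
            identities = np.clip(rng.normal(identity_mean, identity_sd, size=count), 0.0, 100.0)
            lens = np.clip(np.rint(rng.normal(40, 4, size=count)), 20, 50).astype(int)
            for ident, alen in zip(identities, lens):
                read_no += 1
                rows.append(AlignmentRow(
                    query_id=f"{spec.sample_id}_r{read_no:07d}", subject_id=subject,
                    pct_identity=round(float(ident), 1), aln_len=int(alen),
                    mismatches=int(alen * (1 - ident / 100)), gap_opens=0,
                    qstart=1, qend=int(alen) * 3, sstart=1, send=int(alen),
                    evalue=1e-20, bitscore=80.0,
                ))

        total_m = spec.total_reads / 1_000_000
        for sid, cls in classes.items():
            name = cls.name
            kappa = 1.0 if name == "ribosomal_marker" else spec.kappa.get(name, 0.0)
            lam = kappa * (cls.ref_len_bp / 1000) * total_m * marker_rpkm
            count = int(rng.poisson(lam))
            emit(sid, count, PLANTED_IDENTITY[name])
            if name != "ribosomal_marker" and count > 0:
                n_low = int(rng.poisson(lam * low_identity_fraction))
                emit(sid, n_low, 45.0)

        # decoy reads hitting a subject outside every gene class
        lam_decoy = decoy_fraction * (MARKER_LEN_AA * 3 / 1000) * total_m * marker_rpkm * 14
        emit_count = int(rng.poisson(lam_decoy))
        emit("decoy_ref", emit_count, 70.0)

        rng.shuffle(rows)
        hits[spec.sample_id] = rows
        truth_rows.append({
            "sample_id": spec.sample_id,
            "kappa_coxL": spec.kappa.get("coxL", 0.0),
            "kappa_cooS": spec.kappa.get("cooS", 0.0),
            "kappa_cdhA": spec.kappa.get("cdhA", 0.0),
            "expected_ratio": np.nan if spec.expected_ratio is None else spec.expected_ratio,
            "depth_m": np.nan if spec.depth_m is None else spec.depth_m,
            "o2_uM": np.nan if spec.o2_uM is None else spec.o2_uM,
        })

    metadata = [
        SampleMetadata(sample_id=s.sample_id, total_reads=s.total_reads,
                       depth_m=s.depth_m, o2_uM=s.o2_uM, habitat=s.habitat)
        for s in samples
    ]
    return MetagenomeSet(hits=hits, metadata=metadata,
                         truth=pd.DataFrame(truth_rows),
                         subject_class=classes, marker_subjects=MARKER_SUBJECTS)
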