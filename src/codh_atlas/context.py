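"""Genome-neighbourhood analysis of CODH loci.

For every CODH gene the +/-15-gene window on the same contig is collected,
neighbouring CDS are annotated with their best COG (RPS-style hits filtered
at e-value < 1e-6), and the locus is assigned a functional group from a
prioritised trigger table (Wood-Ljungdahl pathway, one-carbon pool, ECH,
FNOR/CooF electron carriers, ... down to "standalone" when no known
CO-metabolism partner is nearby).

Wood-Ljungdahl logic mirrors the biology: a proximal acsB/cdhC (the
catalytic ACS beta subunit) places the locus in the WLP group outright;
proximal cdhB/D/E subunits with acsB/cdhC elsewhere in the genome (detected
by a filtered HMM search: E <= 1e-30, 350-762 aa for COG1614) also count as
WLP, while the same neighbourhood without any genome-level acsB/cdhC is an
"incomplete acs cluster".

For Mo-CODH, the coxM-coxS-coxL operon arrangement is detected around each
coxL locus and the quinone-shuttle gene coxG is scored as proximal (within
the window), distant (genome-level HMM hit: E <= 1e-30, 150-450 aa for
COG3427) or absent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Mapping, Optional, Sequence

import yaml

from .io_formats import AlignmentRow, CdsRecord, HmmHitRow

COG_EVALUE_MAX = 1e-6        # exclusive: e-value < 1e-6
HMM_EVALUE_MAX = 1e-30       # inclusive: E <= 1e-30
HMM_LENGTH_WINDOWS = {"COG1614": (350, 762), "COG3427": (150, 450)}
DEFAULT_WINDOW = 15

COX_ROLE_TOKENS = {
    "coxM": ("COG1319", "coxm"),
    "coxS": ("COG2080", "coxs"),
    "coxL": ("COG1529", "coxl"),
    "coxG": ("COG3427", "coxg"),
}


@dataclass(frozen=True)
class FunctionalRule:
    group: str
    priority: int
    trigger_cogs: frozenset[str] = frozenset()
    trigger_keywords: tuple[str, ...] = ()


@dataclass(frozen=True)
class ContextAssignment:
    codh_protein_id: str
    genome_id: str
    group: str
    evidence: tuple[str, ...] = ()          # triggering CDS protein/product ids
    distant_partner: Optional[str] = None   # acsB_cdhA_distant or coxG_distant
    neighborhood_size: int = 0


@dataclass(frozen=True)
class CoxOperonCall:
    coxL_id: str
    structure: str     # MSL_complete | SL_partial | L_only | other_order
    coxG_status: str   # proximal | distant | absent


def load_ni_ruleset(path: Optional[str] = None) -> list[FunctionalRule]:
    """Load the Ni functional-group trigger table (shipped default or a file)."""
    if path is None:
        text = resources.files("codh_atlas.data").joinpath("ni_context_rules.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)["groups"]
    rules = [
        FunctionalRule(
            group=entry["group"],
            priority=int(entry["priority"]),
            trigger_cogs=frozenset(entry.get("cogs") or ()),
            trigger_keywords=tuple(k.lower() for k in (entry.get("keywords") or ())),
        )
        for entry in raw
    ]
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ValueError("ruleset priorities must be unique")
    return sorted(rules, key=lambda r: r.priority)


# ---------------------------------------------------------------------------
# COG assignment and neighbourhoods
# ---------------------------------------------------------------------------

def filter_cog_annotations(hits: Sequence[AlignmentRow]) -> dict[str, str]:
    """Best COG per CDS at e-value < 1e-6.

    Ties broken by lower e-value, then higher bit score, then lexicographic
    COG id. CDS whose best hit misses the threshold get no assignment.
    """
    best: dict[str, AlignmentRow] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.bitscore, h.subject_id) < (cur.evalue, -cur.bitscore, cur.subject_id):
            best[h.query_id] = h
    return {
        cds_id: h.subject_id
        for cds_id, h in best.items()
        if h.evalue < COG_EVALUE_MAX
    }


def neighborhood(
    cds_table: Sequence[CdsRecord],
    focal: CdsRecord,
    window: int = DEFAULT_WINDOW,
) -> list[CdsRecord]:
    """All CDS within ``window`` positions of the focal CDS on its contig.

    Windows truncate silently at contig edges (fragmented MAGs are expected).
    The focal CDS is included. Raises ``KeyError`` if it is not in the table.
    """
    if focal not in cds_table:
        raise KeyError(f"focal CDS {focal.protein_id or focal.cds_index} not in table")
    return [
        c for c in cds_table
        if c.genome_id == focal.genome_id
        and c.contig_id == focal.contig_id
        and abs(c.cds_index - focal.cds_index) <= window
    ]


def _keyword_match(keyword: str, product: str) -> bool:
    return re.search(rf"(?<!\w){re.escape(keyword)}(?!\w)", product) is not None


def _triggers_in(
    rule: FunctionalRule,
    neighbors: Sequence[CdsRecord],
    cog_of: Mapping[str, str],
) -> list[str]:
    hits = []
    for cds in neighbors:
        cds_id = cds.protein_id or f"{cds.contig_id}:{cds.cds_index}"
        cog = cds.cog_id or cog_of.get(cds_id)
        product = (cds.product or "").lower()
        if (cog and cog in rule.trigger_cogs) or any(
            _keyword_match(k, product) for k in rule.trigger_keywords
        ):
            hits.append(cds_id)
    return hits


# ---------------------------------------------------------------------------
# Ni functional-group assignment
# ---------------------------------------------------------------------------

def classify_ni_context(
    focal: CdsRecord,
    neighbors: Sequence[CdsRecord],
    ruleset: Sequence[FunctionalRule],
    distant_acsb: bool = False,
    cog_of: Optional[Mapping[str, str]] = None,
) -> ContextAssignment:
    """Assign one functional group to a Ni-CODH locus.

    Deterministic and invariant to neighbour ordering: the highest-priority
    rule with a trigger in the window wins; no trigger means "standalone".
    ``distant_acsb`` reports whether the genome carries an acsB/cdhA
    homologue outside the window (see :func:`resolve_distant_partner`).
    """
    cog_of = cog_of or {}
    focal_id = focal.protein_id or f"{focal.contig_id}:{focal.cds_index}"
    others = [c for c in neighbors if c is not focal]
    by_group = {r.group: r for r in ruleset}

    wlp = by_group.get("WLP")
    incomplete = by_group.get("incomplete_acs_cluster")
    if wlp is not None:
        ev = _triggers_in(wlp, others, cog_of)
        if ev:
            return ContextAssignment(focal_id, focal.genome_id, "WLP",
                                     tuple(ev), None, len(neighbors))
    if incomplete is not None:
        ev = _triggers_in(incomplete, others, cog_of)
        if ev:
            if distant_acsb:
                return ContextAssignment(focal_id, focal.genome_id, "WLP",
                                         tuple(ev), "acsB_cdhA_distant", len(neighbors))
            return ContextAssignment(focal_id, focal.genome_id, "incomplete_acs_cluster",
                                     tuple(ev), None, len(neighbors))

    for rule in sorted(ruleset, key=lambda r: r.priority):
        if rule.group in ("WLP", "incomplete_acs_cluster", "standalone"):
            continue
        ev = _triggers_in(rule, others, cog_of)
        if ev:
            return ContextAssignment(focal_id, focal.genome_id, rule.group,
                                     tuple(ev), None, len(neighbors))
    return ContextAssignment(focal_id, focal.genome_id, "standalone",
                             (), None, len(neighbors))


# ---------------------------------------------------------------------------
# Mo operon structure
# ---------------------------------------------------------------------------

def _cox_role(cds: CdsRecord) -> Optional[str]:
    product = (cds.product or "").lower()
    for role, (cog, token) in COX_ROLE_TOKENS.items():
        if cds.cog_id == cog or _keyword_match(token, product):
            return role
    return None


def detect_cox_operon(
    focal: CdsRecord,
    neighbors: Sequence[CdsRecord],
    distant_coxg: bool = False,
    adjacency_gap: int = 1,
) -> CoxOperonCall:
    """Classify the cox operon arrangement around a coxL locus.

    ``MSL_complete`` requires coxM, coxS and coxL on the same strand in
    transcriptional order M -> S -> L with at most ``adjacency_gap``
    intervening CDS between consecutive genes; ``SL_partial`` an adjacent
    same-strand coxS without coxM; ``other_order`` all three present but not
    in operonic arrangement; ``L_only`` otherwise. coxG is proximal if found
    in the window, else distant when the genome-level HMM gate fired.
    """
    focal_id = focal.protein_id or f"{focal.contig_id}:{focal.cds_index}"
    roles: dict[str, list[CdsRecord]] = {"coxM": [], "coxS": [], "coxG": []}
    for cds in neighbors:
        if cds is focal:
            continue
        role = _cox_role(cds)
        if role in roles:
            roles[role].append(cds)

    sign = 1 if focal.strand == "+" else -1
    max_step = adjacency_gap + 1

    def upstream_of(a: CdsRecord, b: CdsRecord) -> bool:
        # a transcriptionally precedes b, within the adjacency tolerance
        step = (b.cds_index - a.cds_index) * sign
        return 1 <= step <= max_step and a.strand == focal.strand and b.strand == focal.strand

    complete = any(
        upstream_of(m, s) and upstream_of(s, focal)
        for s in roles["coxS"] for m in roles["coxM"]
    )
    if complete:
        structure = "MSL_complete"
    elif roles["coxM"] and roles["coxS"]:
        structure = "other_order"
    elif any(upstream_of(s, focal) for s in roles["coxS"]):
        structure = "SL_partial"
    else:
        structure = "L_only"

    if roles["coxG"]:
        coxg = "proximal"
    elif distant_coxg:
        coxg = "distant"
    else:
        coxg = "absent"
    return CoxOperonCall(coxL_id=focal_id, structure=structure, coxG_status=coxg)


# ---------------------------------------------------------------------------
# Distant-partner HMM gate and multicopy summaries
# ---------------------------------------------------------------------------

def _genome_of_target(target_id: str) -> str:
    # convention: target_id = "<genome>|<protein>"
    return target_id.split("|", 1)[0]


def resolve_distant_partner(
    genome_id: str,
    hmm_hits: Sequence[HmmHitRow],
    profile_id: str,
    genome_of: Callable[[str], str] = _genome_of_target,
) -> bool:
    """True iff the genome has a high-confidence homologue of the profile.

    A hit counts iff E <= 1e-30 and the target length falls inside the
    profile's window (COG1614: 350-762 aa; COG3427: 150-450 aa, inclusive).
    """
    if profile_id not in HMM_LENGTH_WINDOWS:
        raise ValueError(f"unknown HMM profile {profile_id!r}")
    lo, hi = HMM_LENGTH_WINDOWS[profile_id]
    return any(
        h.profile_id == profile_id
        and genome_of(h.target_id) == genome_id
        and h.evalue <= HMM_EVALUE_MAX
        and lo <= h.target_len <= hi
        for h in hmm_hits
    )


def multicopy_summary(
    records: Sequence[tuple[str, Optional[str]]],
) -> tuple[float, dict[str, dict[str, float]]]:
    """Per-genome copy statistics from (genome_id, clade) pairs.

    Returns the fraction of genomes with two or more CODH genes and the
    asymmetric clade co-occurrence matrix ``M[a][b]`` = fraction of genomes
    containing clade ``a`` that also contain clade ``b``.
    """
    genomes: dict[str, list[Optional[str]]] = {}
    for genome_id, clade in records:
        genomes.setdefault(genome_id, []).append(clade)
    n_genomes = len(genomes)
    multicopy_fraction = (
        sum(1 for copies in genomes.values() if len(copies) >= 2) / n_genomes
        if n_genomes else 0.0
    )
    clades = sorted({c for copies in genomes.values() for c in copies if c is not None})
    clade_sets = [set(c for c in copies if c is not None) for copies in genomes.values()]
    matrix: dict[str, dict[str, float]] = {}
    for a in clades:
        with_a = [s for s in clade_sets if a in s]
        matrix[a] = {
            b: (sum(1 for s in with_a if b in s) / len(with_a)) if with_a else 0.0
            for b in clades
        }
    return multicopy_fraction, matrix
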