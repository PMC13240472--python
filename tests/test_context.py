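"""Genome-context analysis: COG gate, windows, group rules, operons, HMM gate."""

import random

import pytest

from codh_atlas import context as ctx
from codh_atlas.io_formats import AlignmentRow, CdsRecord, HmmHitRow


def _rps(query, cog, evalue, bitscore=100.0):
    return AlignmentRow(query_id=query, subject_id=cog, pct_identity=40.0,
                        aln_len=200, mismatches=0, gap_opens=0, qstart=1,
                        qend=200, sstart=1, send=200, evalue=evalue,
                        bitscore=bitscore)


def _cds(idx, product="hypothetical protein", genome="g1", contig="c1",
         strand="+", cog=None, pid=None):
    start = (idx - 1) * 1000 + 1
    return CdsRecord(genome_id=genome, contig_id=contig, cds_index=idx,
                     start=start, end=start + 899, strand=strand,
                     product=product, cog_id=cog,
                     protein_id=pid or f"{genome}|p{idx:03d}")


@pytest.fixture(scope="module")
def ruleset():
    return ctx.load_ni_ruleset()


# ---------------------------------------------------------------------------
# COG filtering
# ---------------------------------------------------------------------------

def test_cog_gate_threshold_is_exclusive():
    assert ctx.filter_cog_annotations([_rps("a", "COG1", 1e-7)]) == {"a": "COG1"}
    assert ctx.filter_cog_annotations([_rps("a", "COG1", 1e-5)]) == {}
    assert ctx.filter_cog_annotations([_rps("a", "COG1", 1e-6)]) == {}  # strict <


def test_cog_gate_picks_lowest_evalue():
    hits = [_rps("a", "COG2", 1e-8), _rps("a", "COG1", 1e-9)]
    assert ctx.filter_cog_annotations(hits) == {"a": "COG1"}


def test_cog_gate_tie_breaks_by_bitscore_then_id():
    hits = [_rps("a", "COG2", 1e-9, 50.0), _rps("a", "COG1", 1e-9, 80.0)]
    assert ctx.filter_cog_annotations(hits) == {"a": "COG1"}
    hits = [_rps("a", "COG2", 1e-9, 80.0), _rps("a", "COG1", 1e-9, 80.0)]
    assert ctx.filter_cog_annotations(hits) == {"a": "COG1"}


# ---------------------------------------------------------------------------
# Neighbourhoods
# ---------------------------------------------------------------------------

def test_neighborhood_truncates_at_contig_start():
    table = [_cds(i) for i in range(1, 40)]
    neigh = ctx.neighborhood(table, table[0], window=15)
    assert [c.cds_index for c in neigh] == list(range(1, 17))


def test_neighborhood_short_contig_returns_whole_contig():
    table = [_cds(i) for i in range(1, 6)]
    assert ctx.neighborhood(table, table[2], window=15) == table


def test_neighborhood_window_zero_is_focal_only():
    table = [_cds(i) for i in range(1, 6)]
    assert ctx.neighborhood(table, table[2], window=0) == [table[2]]


def test_neighborhood_missing_focal_raises():
    table = [_cds(i) for i in range(1, 6)]
    stranger = _cds(99, genome="g2")
    with pytest.raises(KeyError):
        ctx.neighborhood(table, stranger, window=15)


# ---------------------------------------------------------------------------
# Ni functional groups
# ---------------------------------------------------------------------------

def _focal(idx=10):
    return _cds(idx, product="carbon monoxide dehydrogenase CooS")


def test_proximal_cdhc_gives_wlp(ruleset):
    table = [_focal(), _cds(11, product="acetyl-CoA synthase beta subunit")]
    a = ctx.classify_ni_context(table[0], table, ruleset)
    assert a.group == "WLP"


def test_cdh_subunits_without_distant_acsb_is_incomplete(ruleset):
    table = [_focal(), _cds(11, product="acetyl-CoA decarbonylase/synthase complex subunit cdhB")]
    a = ctx.classify_ni_context(table[0], table, ruleset, distant_acsb=False)
    assert a.group == "incomplete_acs_cluster"


def test_cdh_subunits_with_distant_acsb_is_wlp(ruleset):
    table = [_focal(), _cds(11, product="acetyl-CoA decarbonylase/synthase complex subunit cdhD")]
    a = ctx.classify_ni_context(table[0], table, ruleset, distant_acsb=True)
    assert a.group == "WLP"
    assert a.distant_partner == "acsB_cdhA_distant"


def test_one_carbon_pool_from_fdh_and_fold(ruleset):
    table = [_focal(),
             _cds(12, product="formate dehydrogenase alpha subunit"),
             _cds(13, product="methylene-tetrahydrofolate dehydrogenase folD")]
    a = ctx.classify_ni_context(table[0], table, ruleset)
    assert a.group == "one_carbon_pool"


def test_no_trigger_is_standalone(ruleset):
    table = [_focal(), _cds(11), _cds(12, product="MFS permease")]
    a = ctx.classify_ni_context(table[0], table, ruleset)
    assert a.group == "standalone"


def test_cog_only_trigger_via_rps_assignment(ruleset):
    table = [_focal(), _cds(11, product="hypothetical protein")]
    cog_of = {table[1].protein_id: "COG1614"}
    a = ctx.classify_ni_context(table[0], table, ruleset, cog_of=cog_of)
    assert a.group == "WLP"


def test_priority_wlp_beats_lower_groups(ruleset):
    table = [_focal(),
             _cds(11, product="ABC transporter ATP-binding protein"),
             _cds(12, product="acetyl-CoA synthase beta subunit")]
    a = ctx.classify_ni_context(table[0], table, ruleset)
    assert a.group == "WLP"


def test_classification_is_order_invariant(ruleset):
    table = [_focal(),
             _cds(11, product="FAD-NAD(P) oxidoreductase"),
             _cds(12, product="ferredoxin-like protein CooF"),
             _cds(13, product="ABC transporter ATP-binding protein")]
    expected = ctx.classify_ni_context(table[0], table, ruleset).group
    rng = random.Random(0)
    for _ in range(5):
        shuffled = table[:]
        rng.shuffle(shuffled)
        assert ctx.classify_ni_context(table[0], shuffled, ruleset).group == expected
    assert expected == "FNOR"  # highest-priority trigger present


# ---------------------------------------------------------------------------
# cox operons
# ---------------------------------------------------------------------------

def _cox(idx, role, strand="+"):
    names = {"M": "aerobic CO dehydrogenase medium subunit coxM",
             "S": "aerobic CO dehydrogenase small subunit coxS",
             "L": "aerobic CO dehydrogenase large subunit coxL",
             "G": "CO dehydrogenase accessory protein coxG"}
    return _cds(idx, product=names[role], strand=strand)


def test_msl_complete_plus_strand():
    table = [_cox(10, "M"), _cox(11, "S"), _cox(12, "L")]
    call = ctx.detect_cox_operon(table[2], table)
    assert call.structure == "MSL_complete"


def test_msl_complete_minus_strand_reversed_genomic_order():
    table = [_cox(10, "L", "-"), _cox(11, "S", "-"), _cox(12, "M", "-")]
    call = ctx.detect_cox_operon(table[0], table)
    assert call.structure == "MSL_complete"


def test_sl_partial_and_l_only():
    table = [_cox(11, "S"), _cox(12, "L")]
    assert ctx.detect_cox_operon(table[1], table).structure == "SL_partial"
    solo = [_cox(12, "L")]
    assert ctx.detect_cox_operon(solo[0], solo).structure == "L_only"


def test_all_three_reordered_is_other_order():
    table = [_cox(10, "S"), _cox(11, "M"), _cox(12, "L")]
    assert ctx.detect_cox_operon(table[2], table).structure == "other_order"


def test_strand_mismatch_breaks_operon():
    table = [_cox(10, "M"), _cox(11, "S", "-"), _cox(12, "L")]
    assert ctx.detect_cox_operon(table[2], table).structure == "other_order"


def test_adjacency_gap_tolerates_one_intervening_cds():
    table = [_cox(10, "M"), _cds(11), _cox(12, "S"), _cox(13, "L")]
    assert ctx.detect_cox_operon(table[3], table).structure == "MSL_complete"
    far = [_cox(7, "M"), _cox(10, "S"), _cox(13, "L")]
    assert ctx.detect_cox_operon(far[2], far).structure == "other_order"


def test_coxg_status_resolution():
    table = [_cox(12, "L"), _cox(14, "G")]
    assert ctx.detect_cox_operon(table[0], table).coxG_status == "proximal"
    solo = [_cox(12, "L")]
    assert ctx.detect_cox_operon(solo[0], solo, distant_coxg=True).coxG_status == "distant"
    assert ctx.detect_cox_operon(solo[0], solo, distant_coxg=False).coxG_status == "absent"


# ---------------------------------------------------------------------------
# Distant-partner HMM gate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "profile,evalue,length,expected",
    [
        ("COG3427", 1e-31, 300, True),
        ("COG3427", 1e-30, 300, True),    # inclusive E-value bound
        ("COG3427", 1e-29, 300, False),
        ("COG3427", 1e-40, 149, False),
        ("COG3427", 1e-40, 150, True),
        ("COG3427", 1e-40, 450, True),
        ("COG3427", 1e-40, 451, False),
        ("COG1614", 1e-40, 349, False),
        ("COG1614", 1e-40, 350, True),
        ("COG1614", 1e-40, 762, True),
        ("COG1614", 1e-40, 763, False),
    ],
)
def test_distant_partner_gate_boundaries(profile, evalue, length, expected):
    hits = [HmmHitRow(target_id="g1|p1", profile_id=profile,
                      evalue=evalue, target_len=length)]
    assert ctx.resolve_distant_partner("g1", hits, profile) is expected


def test_distant_partner_unknown_profile_raises():
    with pytest.raises(ValueError, match="unknown HMM profile"):
        ctx.resolve_distant_partner("g1", [], "COG0001")


def test_distant_partner_respects_genome_identity():
    hits = [HmmHitRow(target_id="g2|p1", profile_id="COG3427",
                      evalue=1e-40, target_len=300)]
    assert not ctx.resolve_distant_partner("g1", hits, "COG3427")


# ---------------------------------------------------------------------------
# Multicopy statistics
# ---------------------------------------------------------------------------

def test_multicopy_fraction_simple():
    pairs = [(f"g{i}", "E") for i in range(10)]
    pairs += [("g0", "A"), ("g1", "F")]  # two genomes get a second copy
    frac, _ = ctx.multicopy_summary(pairs)
    assert frac == pytest.approx(0.2)


def test_cooccurrence_single_clade_dataset():
    pairs = [("g0", "E"), ("g1", "E"), ("g2", "E")]
    _, m = ctx.multicopy_summary(pairs)
    assert m == {"E": {"E": 1.0}}


def test_cooccurrence_matrix_matches_bruteforce(ni_context_set):
    truth = ni_context_set.truth
    pairs = []
    for row in truth.itertuples():
        pairs.append((row.genome_id, row.clade))
        if row.n_codh >= 2 and isinstance(row.clade2, str):
            pairs.append((row.genome_id, row.clade2))
    frac, matrix = ctx.multicopy_summary(pairs)

    # brute force directly over the truth table
    genomes = {}
    for g, c in pairs:
        genomes.setdefault(g, set()).add(c)  # noqa: simplified per-genome clade sets
    expected_frac = sum(
        1 for row in truth.itertuples() if row.n_codh >= 2
    ) / len(truth)
    assert frac == pytest.approx(expected_frac)
    clades = sorted({c for s in genomes.values() for c in s})
    for a in clades:
        with_a = [s for s in genomes.values() if a in s]
        for b in clades:
            expected = sum(1 for s in with_a if b in s) / len(with_a)
            assert matrix[a][b] == pytest.approx(expected)
    # asymmetry is possible and the diagonal is exact
    for a in clades:
        assert matrix[a][a] == 1.0
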