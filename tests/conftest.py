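import pandas as pd
import pytest

from codh_atlas import synthetic_data as synth


@pytest.fixture(scope="session")
def ni_profile():
    return synth.make_reference_profile("ni")


@pytest.fixture(scope="session")
def mo_profile():
    return synth.make_reference_profile("mo")


@pytest.fixture(scope="session")
def ni_seqset():
    """Small mixed-defect Ni candidate set with truth table."""
    return synth.make_codh_sequences(60, "ni", seed=11)


@pytest.fixture(scope="session")
def mo_seqset():
    return synth.make_codh_sequences(60, "mo", seed=12)


@pytest.fixture(scope="session")
def ni_context_set():
    return synth.make_context_tables(60, seed=13)


@pytest.fixture(scope="session")
def supplementary_standin():
    """Synthetic stand-in for a published per-sequence supplementary table.

    Hand-built rows with known context gene lists; not derived from any real
    supplementary data. Expected statistics are computed by hand in the
    tests that consume this fixture.
    """
    s1 = pd.DataFrame([
        # genome, clade, neighbour genes, distant acsB flag
        {"protein_id": "n1", "genome_id": "gA", "clade": "A",
         "context_genes": "hypothetical protein;acetyl-CoA synthase beta subunit",
         "distant_acsb": False},
        {"protein_id": "n2", "genome_id": "gA", "clade": "E",
         "context_genes": "hypothetical protein;MFS permease", "distant_acsb": False},
        {"protein_id": "n3", "genome_id": "gB", "clade": "A",
         "context_genes": "acetyl-CoA decarbonylase/synthase complex subunit cdhB",
         "distant_acsb": True},
        {"protein_id": "n4", "genome_id": "gC", "clade": "E",
         "context_genes": "acetyl-CoA decarbonylase/synthase complex subunit cdhD",
         "distant_acsb": False},
        {"protein_id": "n5", "genome_id": "gD", "clade": "E",
         "context_genes": "formate dehydrogenase alpha subunit;hypothetical protein",
         "distant_acsb": False},
        {"protein_id": "n6", "genome_id": "gE", "clade": "F",
         "context_genes": "", "distant_acsb": False},
    ])
    s2 = pd.DataFrame([
        {"protein_id": "m1", "genome_id": "hA",
         "context_genes": ("aerobic CO dehydrogenase medium subunit coxM;"
                           "aerobic CO dehydrogenase small subunit coxS;"
                           "aerobic CO dehydrogenase large subunit coxL"),
         "distant_coxg": False},
        {"protein_id": "m2", "genome_id": "hB",
         "context_genes": ("aerobic CO dehydrogenase small subunit coxS;"
                           "aerobic CO dehydrogenase large subunit coxL;"
                           "CO dehydrogenase accessory protein coxG"),
         "distant_coxg": False},
        {"protein_id": "m3", "genome_id": "hC",
         "context_genes": "aerobic CO dehydrogenase large subunit coxL",
         "distant_coxg": True},
        {"protein_id": "m4", "genome_id": "hD",
         "context_genes": "aerobic CO dehydrogenase large subunit coxL",
         "distant_coxg": False},
    ])
    return s1, s2
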