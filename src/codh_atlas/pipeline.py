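"""End-to-end orchestration: run all stages on a directory of inputs and
write verdicts, D-cluster calls, context assignments, biome calls, abundance
profiles and a dataset summary.

Also provides :func:`reproduce_supplementary`, which re-applies the
classification rules to curated per-sequence tables (the kind of
supplementary data a survey publishes: one row per CODH with its genome,
clade and the gene names found in its neighbourhood) and recomputes the
headline counts — total sequences, functional-group histogram, multicopy
fraction, cox operon completeness and coxG proximity — so a published table
can be checked for internal consistency against the printed numbers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import abundance as ab
from . import biomes as bm
from . import context as ctx
from . import curation as cur
from . import dcluster as dc
from . import io_formats as io
from . import synthetic_data as synth


@dataclass
class RunConfig:
    """Paths and thresholds for a full pipeline run.

    Threshold defaults are the survey's values: length >= 400 aa (Ni) /
    700 aa (Mo), bit score >= 200, RPS e < 1e-6, HMM E <= 1e-30 with length
    windows 350-762 aa (acsB/cdhA) and 150-450 aa (coxG), +/-15-gene
    windows, read filters of 32 aa and 50%/60% identity, 14 ribosomal
    markers.
    """

    indir: Path
    outdir: Path
    seed: int = 0
    window: int = 15
    coverage_threshold: float = 0.5
    strict_motif: bool = False
    expected_markers: int = 14
    run_curation: bool = True
    run_dcluster: bool = True
    run_context: bool = True
    run_biomes: bool = True
    run_abundance: bool = True


def _summarise(counts: Mapping[str, int]) -> dict:
    return dict(sorted(counts.items()))


def run_synthetic(
    outdir: str | Path,
    seed: int = 0,
    n_sequences: int = 300,
    n_genomes: int = 120,
    total_reads: int = 200_000,
) -> dict:
    """Generate a full synthetic dataset, run every stage, write outputs.

    Returns the summary dictionary (also written as ``summary.json``).
    Outputs are pure functions of (sizes, seed): re-running with the same
    arguments reproduces them byte for byte.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed}

    # --- curation + D-cluster, both families -------------------------------
    for family in ("ni", "mo"):
        seqset = synth.make_codh_sequences(n_sequences, family, seed=seed + (0 if family == "ni" else 1))
        io.write_fasta(seqset.records, outdir / f"{family}_candidates.fasta")
        io.write_alignment_table(seqset.hits, outdir / f"{family}_hits.tsv")
        seqset.truth.to_csv(outdir / f"{family}_truth.tsv", sep="\t", index=False)

        verdicts = cur.curate(seqset.records, seqset.hits, seqset.profile,
                              strict_motif=False)
        vdf = pd.DataFrame([
            {"record_id": v.record_id, "family": v.family,
             "passed": v.passed, "failed_rules": ";".join(v.failed_rules)}
            for v in verdicts
        ])
        vdf.to_csv(outdir / f"{family}_verdicts.tsv", sep="\t", index=False)
        summary[f"{family}_candidates"] = len(seqset.records)
        summary[f"{family}_curated"] = int(vdf["passed"].sum())

        if family == "ni":
            calls = []
            by_id = {r.id: r for r in seqset.records}
            passing = [v.record_id for v in verdicts if v.passed]
            for rid in passing:
                rec = by_id[rid]
                pos_map = cur.anchor_to_reference(rec, seqset.profile)
                window = dc.extract_dcluster_window(rec, pos_map, seqset.profile)
                calls.append(dc.classify_dcluster(window, record_id=rid))
            ddf = pd.DataFrame([
                {"record_id": c.record_id, "dtype": c.dtype,
                 "cys_positions": ";".join(map(str, c.cys_positions)),
                 "spacing": "" if c.spacing is None else c.spacing}
                for c in calls
            ])
            ddf.to_csv(outdir / "ni_dcalls.tsv", sep="\t", index=False)
            summary["ni_dcluster_histogram"] = _summarise(
                ddf["dtype"].value_counts().to_dict()) if len(ddf) else {}

    # --- genome context -----------------------------------------------------
    ruleset = ctx.load_ni_ruleset()
    ctxset = synth.make_context_tables(n_genomes, seed=seed + 2)
    io.write_context_table(ctxset.cds, outdir / "ni_context.tsv")
    io.write_hmm_hits(ctxset.hmm_hits, outdir / "ni_hmm_hits.tsv")
    io.write_alignment_table(ctxset.rps_hits, outdir / "ni_rps_hits.tsv")
    ctxset.truth.to_csv(outdir / "ni_context_truth.tsv", sep="\t", index=False)

    cog_of = ctx.filter_cog_annotations(ctxset.rps_hits)
    by_genome: dict[str, list[io.CdsRecord]] = {}
    for cds in ctxset.cds:
        by_genome.setdefault(cds.genome_id, []).append(cds)

    assignments = []
    for row in ctxset.truth.itertuples():
        table = by_genome[row.genome_id]
        focal = next(c for c in table if c.protein_id == row.focal_protein_id)
        neigh = ctx.neighborhood(table, focal, window=15)
        distant = ctx.resolve_distant_partner(row.genome_id, ctxset.hmm_hits, "COG1614")
        assignments.append(ctx.classify_ni_context(focal, neigh, ruleset,
                                                   distant_acsb=distant, cog_of=cog_of))
    adf = pd.DataFrame([
        {"codh_protein_id": a.codh_protein_id, "genome_id": a.genome_id,
         "group": a.group, "evidence": ";".join(a.evidence),
         "distant_partner": a.distant_partner or ""}
        for a in assignments
    ])
    adf.to_csv(outdir / "ni_context_assignments.tsv", sep="\t", index=False)
    summary["ni_context_histogram"] = _summarise(adf["group"].value_counts().to_dict())

    pairs = []
    for row in ctxset.truth.itertuples():
        pairs.append((row.genome_id, row.clade))
        if row.n_codh >= 2 and isinstance(row.clade2, str):
            pairs.append((row.genome_id, row.clade2))
    multicopy_fraction, _ = ctx.multicopy_summary(pairs)
    summary["ni_multicopy_fraction"] = round(multicopy_fraction, 4)

    coxset = synth.make_cox_context_tables(n_genomes, seed=seed + 3)
    io.write_context_table(coxset.cds, outdir / "mo_context.tsv")
    io.write_hmm_hits(coxset.hmm_hits, outdir / "mo_hmm_hits.tsv")
    coxset.truth.to_csv(outdir / "mo_context_truth.tsv", sep="\t", index=False)
    cox_by_genome: dict[str, list[io.CdsRecord]] = {}
    for cds in coxset.cds:
        cox_by_genome.setdefault(cds.genome_id, []).append(cds)
    cox_calls = []
    for row in coxset.truth.itertuples():
        table = cox_by_genome[row.genome_id]
        focal = next(c for c in table if c.protein_id == row.focal_protein_id)
        neigh = ctx.neighborhood(table, focal, window=15)
        distant = ctx.resolve_distant_partner(row.genome_id, coxset.hmm_hits, "COG3427")
        cox_calls.append(ctx.detect_cox_operon(focal, neigh, distant_coxg=distant))
    cdf = pd.DataFrame([
        {"coxL_id": c.coxL_id, "structure": c.structure, "coxG_status": c.coxG_status}
        for c in cox_calls
    ])
    cdf.to_csv(outdir / "mo_operon_calls.tsv", sep="\t", index=False)
    summary["mo_operon_histogram"] = _summarise(cdf["structure"].value_counts().to_dict())
    summary["mo_coxg_histogram"] = _summarise(cdf["coxG_status"].value_counts().to_dict())

    # --- abundance ----------------------------------------------------------
    specs = synth.default_o2_gradient_samples(total_reads=total_reads)
    meta_set = synth.make_metagenome(specs, seed=seed + 4)
    io.write_sample_metadata(meta_set.metadata, outdir / "samples.tsv")
    profiles = []
    for meta in meta_set.metadata:
        io.write_alignment_table(meta_set.hits[meta.sample_id],
                                 outdir / f"hits_{meta.sample_id}.tsv")
        profiles.append(ab.profile_sample(
            meta_set.hits[meta.sample_id], meta,
            meta_set.subject_class, meta_set.marker_subjects))
    rdf = ab.ratio_profile(profiles)
    rdf.to_csv(outdir / "abundance_profiles.tsv", sep="\t", index=False)
    defined = rdf[rdf["ratio_defined"]]
    summary["abundance_samples"] = len(rdf)
    summary["ratio_surface"] = None if defined.empty else round(float(defined.iloc[0]["ratio_mo_ni"]), 3)
    summary["ratio_deepest"] = None if defined.empty else round(float(defined.iloc[-1]["ratio_mo_ni"]), 3)

    # --- biomes -------------------------------------------------------------
    biome_examples = [
        ("G0001", "hydrothermal vent chimney", "Mid-Atlantic Ridge", None),
        ("G0002", "coastal sediment", "Bay of Bengal", None),
        ("G0003", "seawater", "North Pacific", 150.0),
        ("G0004", "solar saltern pond", "", None),
        ("G0005", "soil", "", None),
    ]
    calls = [bm.classify_biome(src, geo, depth, genome_id=g)
             for g, src, geo, depth in biome_examples]
    bdf = pd.DataFrame([{"genome_id": c.genome_id, "biome": c.biome,
                         "sub": c.sub or ""} for c in calls])
    bdf.to_csv(outdir / "biome_calls.tsv", sep="\t", index=False)
    summary["biome_histogram"] = _summarise(bdf["biome"].value_counts().to_dict())

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# Supplementary-table consistency
# ---------------------------------------------------------------------------

DEFAULT_S1_COLUMNS = {
    "protein_id": "protein_id",
    "genome_id": "genome_id",
    "clade": "clade",
    "context_genes": "context_genes",       # ";"-separated neighbour gene names
    "distant_acsb": "distant_acsb",         # optional boolean column
}
DEFAULT_S2_COLUMNS = {
    "protein_id": "protein_id",
    "genome_id": "genome_id",
    "context_genes": "context_genes",       # neighbour genes in positional order
    "distant_coxg": "distant_coxg",
}


def _pseudo_neighbourhood(genes: Sequence[str], genome: str) -> list[io.CdsRecord]:
    records = []
    for i, name in enumerate(genes, start=1):
        start = (i - 1) * 1000 + 1
        records.append(io.CdsRecord(
            genome_id=genome, contig_id="supp", cds_index=i,
            start=start, end=start + 899, strand="+",
            product=name, cog_id=None, protein_id=f"{genome}|s{i:03d}",
        ))
    return records


def reproduce_supplementary(
    s1: Optional[pd.DataFrame],
    s2: Optional[pd.DataFrame],
    expected: Optional[Mapping[str, float]] = None,
    s1_columns: Optional[Mapping[str, str]] = None,
    s2_columns: Optional[Mapping[str, str]] = None,
    ruleset: Optional[Sequence[ctx.FunctionalRule]] = None,
) -> pd.DataFrame:
    """Recompute headline dataset statistics from per-sequence tables.

    ``s1`` is a Ni-CODH table (one row per sequence: genome, clade,
    neighbourhood gene names, optional distant-acsB flag); ``s2`` the
    Mo-CODH analogue with a distant-coxG flag. The classification rules are
    re-applied to the context columns and the recomputed statistics are
    compared against ``expected`` values when given (a tolerance of 2% or
    one count, whichever is larger).
    """
    cols1 = {**DEFAULT_S1_COLUMNS, **(s1_columns or {})}
    cols2 = {**DEFAULT_S2_COLUMNS, **(s2_columns or {})}
    ruleset = ruleset or ctx.load_ni_ruleset()
    stats: dict[str, float] = {}

    if s1 is not None:
        missing = {cols1["protein_id"], cols1["genome_id"], cols1["context_genes"]} - set(s1.columns)
        if missing:
            raise ValueError(f"Ni table missing columns {sorted(missing)}; adjust s1_columns")
        stats["ni_total_sequences"] = float(len(s1))
        stats["ni_total_genomes"] = float(s1[cols1["genome_id"]].nunique())
        groups = []
        for row in s1.itertuples(index=False):
            rowd = row._asdict() if hasattr(row, "_asdict") else dict(zip(s1.columns, row))
            genes = [g for g in str(rowd[cols1["context_genes"]]).split(";") if g and g != "nan"]
            genome = str(rowd[cols1["genome_id"]])
            table = _pseudo_neighbourhood(genes, genome)
            focal = io.CdsRecord(genome_id=genome, contig_id="supp", cds_index=0,
                                 start=1, end=900, strand="+",
                                 product="carbon monoxide dehydrogenase",
                                 protein_id=str(rowd[cols1["protein_id"]]))
            distant = bool(rowd.get(cols1["distant_acsb"], False)) if cols1["distant_acsb"] in s1.columns else False
            assignment = ctx.classify_ni_context(focal, table + [focal], ruleset,
                                                 distant_acsb=distant)
            groups.append(assignment.group)
        hist = pd.Series(groups).value_counts()
        stats["ni_wlp_fraction"] = float(hist.get("WLP", 0)) / len(s1)
        stats["ni_standalone_fraction"] = float(hist.get("standalone", 0)) / len(s1)
        genome_counts = s1[cols1["genome_id"]].value_counts()
        stats["ni_multicopy_fraction"] = float((genome_counts >= 2).sum()) / len(genome_counts)

    if s2 is not None:
        missing = {cols2["protein_id"], cols2["genome_id"], cols2["context_genes"]} - set(s2.columns)
        if missing:
            raise ValueError(f"Mo table missing columns {sorted(missing)}; adjust s2_columns")
        stats["mo_total_sequences"] = float(len(s2))
        structures, coxg_statuses = [], []
        for row in s2.itertuples(index=False):
            rowd = row._asdict() if hasattr(row, "_asdict") else dict(zip(s2.columns, row))
            genes = [g for g in str(rowd[cols2["context_genes"]]).split(";") if g and g != "nan"]
            genome = str(rowd[cols2["genome_id"]])
            table = _pseudo_neighbourhood(genes, genome)
            focal = next((c for c in table if "coxl" in c.product.lower()), None)
            distant = bool(rowd.get(cols2["distant_coxg"], False)) if cols2["distant_coxg"] in s2.columns else False
            if focal is None:
                structures.append("L_only")
                coxg_statuses.append("distant" if distant else "absent")
                continue
            call = ctx.detect_cox_operon(focal, table, distant_coxg=distant)
            structures.append(call.structure)
            coxg_statuses.append(call.coxG_status)
        sh = pd.Series(structures).value_counts()
        gh = pd.Series(coxg_statuses).value_counts()
        stats["mo_msl_complete_count"] = float(sh.get("MSL_complete", 0))
        stats["mo_coxg_proximal_count"] = float(gh.get("proximal", 0))
        stats["mo_coxg_distant_count"] = float(gh.get("distant", 0))
        stats["mo_coxg_any_fraction"] = float(gh.get("proximal", 0) + gh.get("distant", 0)) / len(s2)

    rows = []
    for name, value in sorted(stats.items()):
        exp = None if expected is None else expected.get(name)
        if exp is None:
            match = None
        else:
            tol = max(abs(exp) * 0.02, 1.0 if value == int(value) and exp == int(exp) else 0.02)
            match = bool(abs(value - exp) <= tol)
        rows.append({"statistic": name, "recomputed": value,
                     "expected": math.nan if exp is None else exp, "match": match})
    return pd.DataFrame(rows)
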