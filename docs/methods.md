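# Methods

This note documents the models, rules and design choices behind each
module, what the synthetic data does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Curation model

Candidates are filtered before validation:

* **Length** — raw amino-acid length ≥ 400 (Ni-CODH) or ≥ 700 (Mo-CODH
  CoxL). The exclusion rules are phrased as "length < threshold", so
  boundary values (exactly 400/700) are retained. Raw length is used rather
  than alignment coverage, matching the parenthetical definition of the
  rule.
* **Bit score** — best homology-search bit score ≥ 200 ("< 200 excluded",
  again literal, so 200.0 survives).
* **Redundancy** — 100%-identical residue strings collapse to the
  first-seen id; determinism is the only reason for that tie-break.

Ni-CODH validation is structural. Each candidate is anchored to a reference
scaffold by global pairwise alignment (BLOSUM62, affine gaps, open 11 /
extend 1 — standard protein-homology scoring) and three rules apply:

* all five **C-cluster ligand positions** must map onto a candidate
  cysteine (gap or substitution fails the candidate; a glutamate at a
  ligand position marks the inactive iron-oxo variant);
* the **B- and D-cluster regions** must retain ≥ 50% alignment coverage.
  The source rule is only "no deletion", so deletion is operationalised as
  region coverage below a configurable 50% threshold;
* candidates whose alignment score falls below a configurable floor are
  reported "unalignable" rather than silently classified.

The five ligand positions and the region bounds live in
`ReferenceProfile` as configuration, not code: only one ligand position is
commonly cited in the literature by structural numbering, so the full set
is deliberately user-editable. All shipped profiles are synthetic scaffolds
(labelled as such) whose planted positions are known exactly; pipeline
correctness is therefore independent of any particular structural
constants.

Mo-CODH validation is a motif scan over the whole sequence (no positional
window, first match wins). Permissive mode requires the invariant residues
`xYxCSxR`; strict mode the full `[AS]YRCS[FL]R` alternation. A sequence
with the Form II signature `AYRGAGR` and no Form I match fails as
`form_ii`; with neither, `motif_absent`. Both modes exist because the
tolerated "limited variation" of the motif is not enumerated anywhere;
permissive is the default.

## D-cluster typing

Spacing counts residues strictly between two cysteines (`Cys-x3-Cys` ⇒
spacing 3). The classification is total: 0 cysteines → type V, 1 → IV, and
for ≥ 2 the consecutive cysteine pairs are evaluated with priority
I (spacing 3) > III (spacing 2) > II (spacing 7–16); the tight,
structurally characterised motifs win when several pairs match. Spacings of
1, 4–6 or > 16 with no better pair are surfaced as `unclassified`, never
forced into a type. The search window is the candidate substring aligning
into the profile's D-cluster region plus a 5-residue flank on each side —
the window placement is a package decision, since no boundary definition
exists for the motif.

## Genome context

COG assignment keeps the best RPS hit per CDS iff e < 10⁻⁶ (strict
inequality; ties by lower e-value, higher bit score, lexicographic id).
Neighbourhoods are all CDS within ±15 positions on the same contig; windows
truncate silently at contig edges because fragmented MAG assemblies are the
norm, and a truncated window biases toward `standalone`/partial calls
rather than erroring.

Functional groups come from a prioritised trigger table
(`data/ni_context_rules.yaml`): the highest-priority rule with a trigger
gene in the window wins, and no trigger means `standalone`. The priority
order (WLP > incomplete acs cluster > One Carbon Pool > ECH > F420
hydrogenase > FNOR > CooF > heterodisulfide reductase > NADH:ubiquinone >
CooC > CooA > ABC transporter > glycine cleavage > hybrid/other >
standalone) encodes the judgement that specific metabolic couplings outrank
generic accessory genes; it is config, not code. Wood–Ljungdahl logic is
special-cased: proximal acsB/cdhC → WLP outright; proximal cdhB/D/E with a
genome-level acsB/cdhA homologue (HMM gate below) → WLP with
`distant_partner` recorded; the same neighbourhood without one →
`incomplete_acs_cluster`. Trigger matching accepts either an exact COG id
or a case-insensitive word-boundary keyword in the product text; the
shipped COG↔gene-name table is a best-effort reconstruction and unknown
vocabularies should be reconciled by editing the YAML, never guessed
silently.

cox operons: `MSL_complete` requires coxM, coxS, coxL on one strand in
transcriptional order M→S→L with at most one intervening CDS between
consecutive genes (an "operon" implies co-transcription, hence the strand
requirement; the adjacency tolerance is configurable). All three genes
present but re-ordered → `other_order`; an adjacent same-strand coxS
without coxM → `SL_partial`; otherwise `L_only`. coxG is `proximal` when
inside the window, `distant` when the genome-level HMM gate fires, else
`absent`.

The distant-partner HMM gate retains hits with E ≤ 10⁻³⁰ (inclusive) whose
target length falls inside the profile's window: 350–762 aa for acsB/cdhA
(COG1614), 150–450 aa for coxG (COG3427), both inclusive. The reduced hit
table carries no genome column, so the convention `target_id =
"<genome>|<protein>"` is used, overridable via the `genome_of` argument.

## Abundance statistics

Reads are reduced to best hits (highest bit score, ties by lower e-value,
then first occurrence), then filtered: alignment length ≥ 32 residues and
percent identity ≥ the gene class threshold (60% coxL; 50% cooS, cdhA and
ribosomal markers). All thresholds are inclusive ("minimum of"). The
initial 50% screen and the gene-specific Ni filters coincide at 50%, so
they are implemented as a single inclusive pass.

RPKM = count / ((L/1000) · (total/10⁶)) with L in nucleotides; where only
protein references exist, L = 3 × protein length (reads are nucleotide,
the database protein, as in blastx-style searches). Average gene copies
per organism divides a gene's RPKM by the arithmetic mean RPKM of exactly
14 universal single-copy ribosomal proteins (count configurable; the
marker identities are a citation-level detail and are config). The Mo/Ni
ratio is copies(coxL)/(copies(cooS)+copies(cdhA)); zero denominators yield
an undefined, flagged ratio, never infinity. Read pairs are counted as
independent reads.

## Synthetic data

The generator is the package's study-conditions definition, not a tuning
dial.

* **Sequences** — candidates are mutated copies of the reference scaffold:
  ~3% background substitutions away from critical positions plus one
  insertion (3–8 aa) and one deletion (1–3 aa) in a zone downstream of all
  active-site features, so anchoring alignments are non-trivial but the
  planted features' coordinates remain exactly trackable. Each defective
  candidate carries exactly one defect (ligand Cys→Glu, B- or D-region
  deletion, Form II motif, motif loss, or truncation below the length
  gate). The background alphabet excludes cysteine so every Cys is a
  planted one. Default defect mix: 55% valid / 15% ligand mutation / 10%
  B-deletion / 10% D-deletion / 10% short; D-type mix 30/25/25/10/10% for
  types I–V.
* **Contexts** — one contig of 31–35 CDS per genome with the focal gene
  placed so the ±15 window fits; trigger genes are recognisable half via
  COG-only (through the RPS gate, with an above-gate decoy hit planted
  alongside) and half via product text only, so both annotation routes are
  exercised. Gate-violating HMM hits (E = 10⁻²⁹, or lengths one residue
  outside the windows) are planted for negative cases. 20% of genomes carry
  a second, standalone CODH copy for multicopy statistics. Default group
  mix is broad (WLP-proximal 28%, WLP-via-distant 8%, standalone 20%, the
  remaining groups a few percent each); cox structures default to 90%
  MSL-complete, and coxG to 66% proximal / 27% distant / 7% absent.
* **Metagenomes** — per-gene read counts are Poisson with mean
  κ · L_kb · (total/10⁶) · m, where κ is the planted copies-per-organism,
  single-copy markers have κ = 1 and m (default 1000) is the marker RPKM
  scale, chosen once so that κ ≥ 0.01 at 10⁶ reads gives recoverable counts
  over 20 replicates. Identities are normal around the planted class mean
  (75% coxL, 70% cooS/cdhA, 80% markers; sd 3), alignment lengths normal
  (40 ± 4, clipped at 20) so the 32-aa gate removes ~2% uniformly; a 2%
  planted low-identity (45%) read fraction must be removed by the identity
  gates and ~1% decoy reads hit a subject outside every gene class. The
  default oxygen-gradient scenario holds Mo-CODH roughly flat
  (κ ≈ 0.04–0.05) while Ni-CODH rises from 10⁻⁴ to 8·10⁻² as O₂ falls from
  250 to 0.5 µM — a planted ratio span of roughly three orders of
  magnitude; the sediment scenario raises the archaeal (cdhA) share of
  Ni-CODH through 50% at ~50 cm depth.

What the generator does **not** emulate: real sequence evolution
(mutations are i.i.d., no rate heterogeneity or indel clustering inside
domains), homology detection noise (every candidate has a clean best hit),
annotation vocabulary drift (trigger names are drawn from the same table
the classifier uses — context tests validate the mechanism, not the
unpublished trigger vocabulary), read-level artefacts (no sequencing
error model, chimeras or mapping ambiguity) and taxonomic structure.
Passing tests therefore demonstrate rule correctness and statistical
recovery under the stated model, not robustness to the vagaries of real
survey data.

## Problem sizes and numerics

The default test and acceptance runs use 10³ Ni + 300 Mo candidates for
curation recovery, 10⁴ random windows for the D-cluster oracle, 200
genomes per context suite, and 20 Poisson replicates at 10⁶ reads per
sample for abundance recovery — sizes at which every planted-recovery
check is exact and the Monte-Carlo checks have comfortable margins.
Floating-point invariants (RPKM linearity, copies scale-invariance) are
asserted to relative 10⁻¹², i.e. machine precision up to rounding of
non-power-of-two scale factors. Biome depth zones use half-open intervals
[lower, upper) at 200/1000/4000/6000 m.

## Known limitations

* The shipped reference profiles are synthetic scaffolds; real surveys
  must supply structure-derived ligand positions and region bounds in a
  profile of their own.
* The COG/keyword trigger table and the biome keyword dictionary are
  best-effort reconstructions of manual curation steps and are expected to
  be edited per dataset.
* The consistency checker for published per-sequence tables
  (`pipeline.reproduce_supplementary`) assumes a simple schema (one row
  per sequence, a `;`-separated context-gene column); column mappings are
  config, and its tests run on a synthetic stand-in table.
* Abundance estimates inherit Poisson noise: per-sample ratios at planted
  copies below ~10⁻³ per organism are reported but dominated by counting
  error, exactly as in real low-coverage samples.
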