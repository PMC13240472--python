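# Functional-group trigger table for Ni-CODH genome-context classification.
#
# Editable reconstruction: group names follow the published categorisation of
# marine Ni-CODH neighbourhoods; trigger COG ids and gene-name keywords are a
# best-effort mapping and are meant to be reconciled against a user's own
# annotation vocabulary. Keywords are matched case-insensitively on word
# boundaries within the CDS product text; COG ids are matched exactly.
#
# priority 1 is highest. "standalone" is the fallback and must stay last with
# no triggers. WLP vs incomplete_acs_cluster carry special logic in code:
# proximal acsB/cdhC  -> WLP; proximal cdhB/D/E with a distant genome-level
# acsB/cdhA homologue -> WLP, without one -> incomplete_acs_cluster.
groups:
  - group: WLP
    priority: 1
    cogs: [COG1614]
    keywords: [acsb, cdhc, "acetyl-coa synthase beta subunit"]
  - group: incomplete_acs_cluster
    priority: 2
    cogs: [COG1152, COG1456, COG2069]
    keywords: [cdhb, cdhd, cdhe]
  - group: one_carbon_pool
    priority: 3
    cogs: [COG0243, COG2759, COG0190, COG0685]
    keywords: [fdh, "formate dehydrogenase", fhs, fts,
               "formyl-tetrahydrofolate synthase", fold,
               "methylene-tetrahydrofolate dehydrogenase", metf,
               "methylene-tetrahydrofolate reductase"]
  - group: ECH
    priority: 4
    cogs: [COG3261, COG3262]
    keywords: [ech, "energy-converting hydrogenase"]
  - group: F420_hydrogenase
    priority: 5
    cogs: [COG3259]
    keywords: [frh, "f420-reducing hydrogenase"]
  - group: FNOR
    priority: 6
    cogs: [COG1251]
    keywords: [fnor, "fad-nad(p) oxidoreductase"]
  - group: CooF
    priority: 7
    cogs: [COG0437]
    keywords: [coof, "ferredoxin-like protein coof"]
  - group: heterodisulfide_reductase
    priority: 8
    cogs: [COG2048]
    keywords: [hdr, "heterodisulfide reductase"]
  - group: NADH_ubiquinone
    priority: 9
    cogs: [COG0649]
    keywords: [nuo, "nadh:ubiquinone oxidoreductase"]
  - group: CooC
    priority: 10
    cogs: [COG3640]
    keywords: [cooc, "codh maturation nickel chaperone"]
  - group: CooA
    priority: 11
    cogs: []
    keywords: [cooa, "co-sensing transcriptional regulator"]
  - group: ABC_transporter
    priority: 12
    cogs: [COG1131]
    keywords: ["abc transporter"]
  - group: glycine_cleavage
    priority: 13
    cogs: [COG0403, COG0404, COG0509]
    keywords: [gcvp, gcvt, gcvh, "glycine cleavage"]
  - group: hybrid/other
    priority: 14
    cogs: [COG1151]
    keywords: [hcp, "hybrid cluster protein"]
  - group: standalone
    priority: 15
    cogs: []
    keywords: []
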