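"""Map isolation-source metadata strings to marine biomes.

Keyword matching is case-insensitive and longest-match-wins; seawater
records with a depth are placed in standard oceanographic depth zones.
Non-marine or ambiguous entries are excluded rather than guessed.
"""

from codh_atlas import biomes as bm

entries = [
    ("hydrothermal vent chimney", "Mid-Atlantic Ridge", None),
    ("coastal sediment", "Arabian Sea", None),
    ("seawater", "North Pacific subtropical gyre", 150.0),
    ("seawater", "Mariana Trench", 10900.0),
    ("sponge tissue", "Great Barrier Reef", None),
    ("oil field produced water", "North Sea", None),
    ("solar saltern pond", "", None),
    ("soil", "agricultural plot", None),
]

print(f"{'isolation source':30s} {'biome':18s} sub-category")
for source, geo, depth in entries:
    call = bm.classify_biome(source, geo, depth)
    print(f"{source:30s} {call.biome:18s} {call.sub or '-'}")

# "excluded" flags entries outside the marine scheme; the keyword dictionary
# is a YAML config, so site-specific vocabularies can be swapped in.
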