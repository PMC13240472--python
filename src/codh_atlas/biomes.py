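"""Keyword-based mapping of isolation-source metadata to marine biomes.

Seven biomes are recognised: hydrothermal vents, coastal, seawater,
sediment, host-associated, oil fields and solar salterns. Coastal entries
are sub-divided into water and sediment fractions; seawater entries are
sub-divided by depth zone using standard oceanographic bounds (half-open
intervals): epipelagic [0, 200) m, mesopelagic [200, 1000) m, bathypelagic
[1000, 4000) m, abyssopelagic [4000, 6000) m, hadal >= 6000 m.

Matching is case-insensitive over the concatenated isolation-source and
geographic-location fields; when several dictionary keywords occur, the
longest (most specific) match wins, so "coastal sediment" beats both
"coastal" and "sediment". Text with no marine keyword is excluded — the
scheme deliberately drops ambiguous or non-marine entries rather than
guessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import yaml

DEPTH_ZONES = (
    (0.0, 200.0, "epipelagic"),
    (200.0, 1000.0, "mesopelagic"),
    (1000.0, 4000.0, "bathypelagic"),
    (4000.0, 6000.0, "abyssopelagic"),
    (6000.0, float("inf"), "hadal"),
)


@dataclass(frozen=True)
class BiomeCall:
    genome_id: str
    biome: str                 # seven biomes or "excluded"
    sub: Optional[str] = None  # coastal_{water,sediment} or a depth zone


def load_biome_keywords(path: Optional[str] = None) -> dict[str, dict]:
    """Load the keyword dictionary (shipped default or a user file)."""
    if path is None:
        text = resources.files("codh_atlas.data").joinpath("biome_keywords.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)["keywords"]
    return {k.lower(): v for k, v in raw.items()}


def depth_zone(depth_m: float) -> str:
    for lo, hi, name in DEPTH_ZONES:
        if lo <= depth_m < hi:
            return name
    raise ValueError(f"negative depth {depth_m}")


def classify_biome(
    isolation_source: str,
    geo: str = "",
    depth_m: Optional[float] = None,
    genome_id: str = "",
    keywords: Optional[Mapping[str, dict]] = None,
) -> BiomeCall:
    """Assign a biome (and sub-category where applicable) from metadata text."""
    if keywords is None:
        keywords = load_biome_keywords()
    text = f"{isolation_source} {geo}".lower()
    matches = [(len(k), k) for k in keywords if k in text]
    if not matches:
        return BiomeCall(genome_id=genome_id, biome="excluded")
    _, best = max(matches)
    entry = keywords[best]
    biome = entry["biome"]
    sub = entry.get("sub")
    if biome == "seawater":
        sub = depth_zone(depth_m) if depth_m is not None else "unspecified"
    return BiomeCall(genome_id=genome_id, biome=biome, sub=sub)
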