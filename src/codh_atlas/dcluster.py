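"""D-cluster architecture typing for Ni-CODHs.

The accessory D-cluster of Ni-CODH is ligated by zero, one or two cysteines
whose count and spacing define five architectural types:

* type I    Cys-x3-Cys        (spacing 3)
* type II   Cys-x7..16-Cys    (spacing 7-16)
* type III  Cys-x2-Cys        (spacing 2)
* type IV   a single cysteine
* type V    no cysteines

Spacing counts the residues strictly between the two cysteines. Windows with
two or more cysteines are evaluated over consecutive cysteine pairs with
priority I > III > II (the structurally characterised tight motifs win when
several pairs match); spacings of 1, 4-6 or >16 with no better pair leave
the window unclassified rather than forced into a type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .curation import ReferenceProfile
from .io_formats import ProteinRecord

TYPE_I_SPACING = 3
TYPE_III_SPACING = 2
TYPE_II_RANGE = (7, 16)


@dataclass(frozen=True)
class DClusterCall:
    """A D-cluster type assignment and the cysteines that justify it.

    ``cys_positions`` are 1-based indices into the window; ``spacing`` is
    set only for types I-III (residues between the chosen cysteine pair).
    """

    record_id: str
    dtype: str  # one of {"I", "II", "III", "IV", "V", "unclassified"}
    cys_positions: tuple[int, ...] = ()
    spacing: Optional[int] = None


def extract_dcluster_window(
    candidate: ProteinRecord,
    pos_map: Mapping[int, Optional[int]],
    profile: ReferenceProfile,
    flank: int = 5,
) -> str:
    """Candidate substring homologous to the profile's D-cluster region.

    The window spans the candidate positions that align into the reference
    D-cluster region, extended by ``flank`` residues on each side and clipped
    to the sequence. Returns "" if the region is fully gapped.
    """
    if profile.d_cluster_region is None:
        raise ValueError("profile has no D-cluster region")
    lo, hi = profile.d_cluster_region
    mapped = [pos_map.get(p) for p in range(lo, hi + 1)]
    mapped = [m for m in mapped if m is not None]
    if not mapped:
        return ""
    start = max(1, min(mapped) - flank)
    end = min(len(candidate.sequence), max(mapped) + flank)
    return candidate.sequence[start - 1:end]


def classify_dcluster(window: str, record_id: str = "") -> DClusterCall:
    """Assign a D-cluster type to a window string (total function)."""
    cys = tuple(i + 1 for i, aa in enumerate(window) if aa == "C")
    if len(cys) == 0:
        return DClusterCall(record_id, "V", cys)
    if len(cys) == 1:
        return DClusterCall(record_id, "IV", cys)
    spacings = [b - a - 1 for a, b in zip(cys, cys[1:])]
    for target_type, match in (
        ("I", lambda s: s == TYPE_I_SPACING),
        ("III", lambda s: s == TYPE_III_SPACING),
        ("II", lambda s: TYPE_II_RANGE[0] <= s <= TYPE_II_RANGE[1]),
    ):
        for (a, b), s in zip(zip(cys, cys[1:]), spacings):
            if match(s):
                return DClusterCall(record_id, target_type, (a, b), spacing=s)
    return DClusterCall(record_id, "unclassified", cys)
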