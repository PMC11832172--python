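"""The screened MET inhibitor panel and its type classification.

ATP-competitive kinase inhibitors are grouped by binding mode: type I bind
the active (DFG-in) conformation in the adenosine pocket, type II extend
into the back pocket opened in the inactive (DFG-out) conformation, and
type I½ engage both. Tivantinib is carried as "other": its selection
profile tracks the untreated control, consistent with MET-independent
cytotoxicity rather than on-target inhibition.

The mapping is configuration, not code: analyses accept any
``condition -> type`` dict, with this panel as the shipped default.
"""

from __future__ import annotations

DMSO = "DMSO"

TYPE_I = "typeI"
TYPE_II = "typeII"
TYPE_I_HALF = "typeI_half"
TYPE_OTHER = "other"

#: Default inhibitor -> type map for the 11-inhibitor MET panel.
#: Capmatinib and tepotinib are subtype Ia (solvent-front interacting),
#: savolitinib and NVP-BVU972 subtype Ib; the Ia/Ib distinction is recorded
#: in INHIBITOR_SUBTYPE but not used in type-level aggregation.
DEFAULT_TYPE_MAP: dict[str, str] = {
    "crizotinib": TYPE_I,
    "capmatinib": TYPE_I,
    "tepotinib": TYPE_I,
    "glumetinib": TYPE_I,
    "savolitinib": TYPE_I,
    "NVP-BVU972": TYPE_I,
    "cabozantinib": TYPE_II,
    "glesatinib-analog": TYPE_II,
    "merestinib": TYPE_II,
    "AMG-458": TYPE_I_HALF,
    "tivantinib": TYPE_OTHER,
}

INHIBITOR_SUBTYPE: dict[str, str] = {
    "crizotinib": "Ia",
    "capmatinib": "Ia",
    "tepotinib": "Ia",
    "glumetinib": "I",
    "savolitinib": "Ib",
    "NVP-BVU972": "Ib",
}

INHIBITORS: tuple[str, ...] = tuple(DEFAULT_TYPE_MAP)

#: Default condition list: the 11 inhibitors plus the DMSO vehicle control.
DEFAULT_CONDITIONS: tuple[str, ...] = INHIBITORS + (DMSO,)


def conditions_of_type(type_map: dict[str, str], itype: str) -> list[str]:
    """Conditions mapped to inhibitor type ``itype`` (stable order)."""
    return [c for c, t in type_map.items() if t == itype]
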