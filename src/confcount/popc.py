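"""Reference torsion numbering and standard conformer sets for POPC.

The lipid palmitoyloleoylphosphatidylcholine (POPC) is the canonical complex
test molecule for conformer-counting analyses: 43 all-heavy-atom torsions
spanning the headgroup and both acyl chains.  This module records the atom
quadruple defining each torsion (1-based numbering) and the four standard
conformer subsets of decreasing fineness:

* CONF1 — all 43 torsions (finest),
* CONF2 — 28 torsions (two of every three along the chains),
* CONF3 — the 22 odd-numbered torsions,
* CONF4 — the 15 torsions complementary to CONF2 (coarsest).

CONF5-CONF8 use the same subsets with the torsional-state boundaries rotated
by +60 degrees, probing sensitivity to boundary placement.
"""

from __future__ import annotations

from .discretize import ConformerDefinition, TorsionStateBoundaries

__all__ = ["POPC_TORSIONS", "CONF_SUBSETS", "standard_conformer_definitions"]

#: atom quadruples of the 43 POPC torsions, keyed by 1-based torsion index
POPC_TORSIONS = {
    1: ("C12", "N", "C11", "C15"), 2: ("N", "C11", "C15", "O1"),
    3: ("C11", "C15", "O1", "P1"), 4: ("C15", "O1", "P1", "O2"),
    5: ("O1", "P1", "O2", "C1"), 6: ("P1", "O2", "C1", "C2"),
    7: ("O2", "C1", "C2", "O21"), 8: ("C1", "C2", "O21", "C21"),
    9: ("C2", "O21", "C21", "C22"), 10: ("O2", "C1", "C2", "C3"),
    11: ("C1", "C2", "C3", "O31"), 12: ("C2", "C3", "O31", "C31"),
    13: ("C3", "O31", "C31", "C32"), 14: ("O21", "C21", "C22", "C23"),
    15: ("C21", "C22", "C23", "C24"), 16: ("C22", "C23", "C24", "C25"),
    17: ("C23", "C24", "C25", "C26"), 18: ("C24", "C25", "C26", "C27"),
    19: ("C25", "C26", "C27", "C28"), 20: ("C26", "C27", "C28", "C29"),
    21: ("C27", "C28", "C29", "C210"), 22: ("C28", "C29", "C210", "C211"),
    23: ("C29", "C210", "C211", "C212"), 24: ("C210", "C211", "C212", "C213"),
    25: ("C211", "C212", "C213", "C214"), 26: ("C212", "C213", "C214", "C215"),
    27: ("C213", "C214", "C215", "C216"), 28: ("C214", "C215", "C216", "C217"),
    29: ("C215", "C216", "C217", "C218"), 30: ("O31", "C31", "C32", "C33"),
    31: ("C31", "C32", "C33", "C34"), 32: ("C32", "C33", "C34", "C35"),
    33: ("C33", "C34", "C35", "C36"), 34: ("C34", "C35", "C36", "C37"),
    35: ("C35", "C36", "C37", "C38"), 36: ("C36", "C37", "C38", "C39"),
    37: ("C37", "C38", "C39", "C310"), 38: ("C38", "C39", "C310", "C311"),
    39: ("C39", "C310", "C311", "C312"), 40: ("C310", "C311", "C312", "C313"),
    41: ("C311", "C312", "C313", "C314"), 42: ("C312", "C313", "C314", "C315"),
    43: ("C313", "C314", "C315", "C316"),
}

_CONF2 = (2, 3, 5, 6, 8, 9, 11, 12, 14, 15, 17, 18, 20, 21, 23, 24, 26, 27,
          29, 30, 32, 33, 35, 36, 38, 39, 41, 42)

#: 1-based torsion subsets of the standard conformer sets
CONF_SUBSETS = {
    "CONF1": tuple(range(1, 44)),
    "CONF2": _CONF2,
    "CONF3": tuple(i for i in range(1, 44) if i % 2 == 1),
    "CONF4": tuple(i for i in range(1, 44) if i not in _CONF2),
}


def standard_conformer_definitions(shifted: bool = False) -> list:
    """The four standard conformer definitions as 0-based definitions.

    With ``shifted=True`` returns the CONF5-CONF8 variants: same torsion
    subsets, torsional-state boundaries rotated by +60 degrees.
    """
    boundaries = TorsionStateBoundaries()
    offset = 0
    if shifted:
        boundaries = boundaries.shifted(60.0)
        offset = 4
    out = []
    for k, (name, subset) in enumerate(sorted(CONF_SUBSETS.items()), start=1):
        label = f"CONF{k + offset}" if shifted else name
        out.append(ConformerDefinition(
            name=label,
            torsion_subset=tuple(i - 1 for i in subset),
            boundaries=boundaries,
        ))
    return out
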