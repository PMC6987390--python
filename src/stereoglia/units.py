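"""Unit conventions.

All geometry inside the package is in micrometres (um): lengths um,
areas um^2, volumes um^3, length density um^-2 (um of curve per um^3),
numerical density um^-3.  Reports and the bundled reference values use the
conventional tissue units mm/mm^3 and cells/mm^3; the constants below
convert between the two systems.
"""

#: um.um^-3 (= um^-2) -> mm.mm^-3
UM2_TO_MM_PER_MM3 = 1.0e6

#: um^-3 -> mm^-3
PER_UM3_TO_PER_MM3 = 1.0e9


def lv_to_paper_units(lv_per_um2: float) -> float:
    """Length density um^-2 -> mm of curve per mm^3 of tissue."""
    return lv_per_um2 * UM2_TO_MM_PER_MM3


def nv_to_paper_units(nv_per_um3: float) -> float:
    """Numerical density um^-3 -> cells per mm^3."""
    return nv_per_um3 * PER_UM3_TO_PER_MM3
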