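"""Vibrational band assignments for TEMPO-oxidized cellulose / bPEI sponges.

A static lookup used only to label peaks in reports; nothing in the
analysis depends on it.  Positions are approximate literature values for
the cellulose nano-sponge system (TEMPO-oxidized, ultrasonicated cellulose
nanofibers cross-linked with branched polyethyleneimine).
"""

from __future__ import annotations

from typing import Optional

__all__ = ["BAND_ASSIGNMENTS", "assign"]

BAND_ASSIGNMENTS: dict[float, str] = {
    899.0: "C-O-C stretching of glycoside bonds",
    985.0: "in-plane CH rocking",
    1000.0: "in-plane CH rocking",
    1021.0: "C-N stretching of terminal C-NH2 units",
    1031.0: "C-OH stretching, primary alcohol of cellulose",
    1055.0: "C-OH stretching, secondary alcohol (internal standard)",
    1108.0: "asymmetric C-O-C stretching of cellulose rings",
    1159.0: "C-C breathing mode of cellulose rings",
    1203.0: "C-OH / C-CH bending",
    1311.0: "CH2 rocking of amorphous cellulose",
    1370.0: "CH bending",
    1428.0: "CH2 bending",
    1583.0: "COO- deformation of oxidized cellulose",
    1596.0: "N-H deformation of polyethyleneimine",
    1635.0: "HOH bending of adsorbed water",
    1654.0: "amide C=O stretching (-CONH-)",
    1730.0: "free carboxylic C=O stretching",
    2900.0: "CH / CH2 symmetric stretching",
    3242.0: "O(6)H...O(3') interchain hydrogen bond",
    3254.0: "O(6)H...O(3') interchain hydrogen bond",
    3270.0: "O(2)H...O(6) intrachain hydrogen bond",
    3307.0: "N-H stretching",
    3330.0: "O-H stretching",
    3347.0: "N-H stretching of bonded amides in bPEI",
    3360.0: "O(3)H...O(5) intrachain hydrogen bond",
    3374.0: "O(3)H...O(5) intrachain hydrogen bond",
}


def assign(nu: float, tol: float = 8.0) -> Optional[str]:
    """Nearest tabulated assignment within ``tol`` cm^-1, or None."""
    center = min(BAND_ASSIGNMENTS, key=lambda c: abs(c - nu))
    if abs(center - nu) <= tol:
        return BAND_ASSIGNMENTS[center]
    return None
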