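"""Physico-chemical reference tables.

Constants are embedded here (rather than read from data files) so results
are bit-stable across installations.

* ``AVERAGE_MASS``: average residue masses in Dalton (monoisotopic masses are
  NOT used; these are the conventional average masses of the residues, i.e.
  amino acid minus water). A peptide's average mass is the sum of its residue
  masses plus one water.
* ``SIDECHAIN_PKA`` / ``NTERM_PKA`` / ``CTERM_PKA``: EMBOSS-style pKa values
  used for Henderson-Hasselbalch net-charge and isoelectric-point
  calculations.
* ``PHYSCHEM_GROUPS``: the four-way residue classification used for the
  physico-chemical composition feature.
* ``SS_PROPENSITY``: a per-residue secondary-structure propensity class
  (Chou-Fasman-style majority assignment) backing the built-in 3-state
  stand-in predictor.
"""

from __future__ import annotations

AA20 = "ACDEFGHIKLMNPQRSTVWY"

WATER_MASS = 18.01524

AVERAGE_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

# EMBOSS pKa set: termini plus the seven ionizable side chains.
NTERM_PKA = 8.6
CTERM_PKA = 3.6
SIDECHAIN_PKA: dict[str, float] = {
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}
ACIDIC_SIDECHAINS = "DECY"
BASIC_SIDECHAINS = "KRH"

# hydrophobic / polar / acidic / basic partition of the 20 residues
PHYSCHEM_GROUPS: dict[str, str] = {
    "hydrophobic": "AVLIMFWP",
    "polar": "GSTCYNQ",
    "acidic": "DE",
    "basic": "KRH",
}
GROUP_ORDER = ("hydrophobic", "polar", "acidic", "basic")
RESIDUE_GROUP: dict[str, str] = {
    res: group for group, residues in PHYSCHEM_GROUPS.items() for res in residues
}

# Majority secondary-structure class per residue (H helix, E strand, C coil).
SS_PROPENSITY: dict[str, str] = {
    "A": "H", "E": "H", "L": "H", "M": "H", "Q": "H", "K": "H", "R": "H", "H": "H",
    "V": "E", "I": "E", "Y": "E", "C": "E", "W": "E", "F": "E", "T": "E",
    "G": "C", "N": "C", "P": "C", "S": "C", "D": "C",
}
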