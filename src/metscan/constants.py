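"""Shared vocabularies: metals, amino acids, donor-atom chemistry.

The metal vocabulary covers the fourteen elements for which metal-bound
protein structures are catalogued, split into biologically essential metals
and non-essential (toxic) metals.  The split drives the EMB / non-EMB
accounting in :mod:`metscan.census`.
"""

from __future__ import annotations

# Fourteen metals with curated metal-bound structures.
METALS: frozenset[str] = frozenset(
    {"Zn", "Cu", "Ca", "Co", "Fe", "Mg", "Mn", "Ni", "Cd", "Hg", "Pb", "Ba", "Cr", "As"}
)

# Biologically essential metals (EMB = essential-metal-binding).
ESSENTIAL_METALS: frozenset[str] = frozenset({"Zn", "Cu", "Ca", "Co", "Fe", "Mg", "Mn", "Ni"})

# Non-essential / toxic metals (non-EMB).
NON_ESSENTIAL_METALS: frozenset[str] = frozenset({"Cd", "Hg", "Pb", "Ba", "Cr", "As"})

AA_ONE_LETTER: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET: frozenset[str] = frozenset(AA_ONE_LETTER)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# Common non-standard residues mapped to their standard parents.  Residues
# not present here and not standard are excluded from detected sites.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine (closest sequence-expressible parent)
    "CSO": "CYS",  # S-hydroxycysteine
    "CSD": "CYS",  # S-cysteinesulfinic acid
    "CME": "CYS",  # S,S-(2-hydroxyethyl)thiocysteine
    "HIC": "HIS",  # 4-methylhistidine
    "MLY": "LYS",  # N-dimethyllysine
    "PTR": "TYR",  # phosphotyrosine
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "KCX": "LYS",  # N-carboxylysine
    "LLP": "LYS",  # PLP-lysine
    "OCS": "CYS",  # cysteine sulfonic acid
}


def residue_to_one_letter(resname: str) -> str | None:
    """Map a residue name (3-letter, possibly non-standard) to one letter.

    Returns None for residues that cannot be expressed as a standard
    amino acid (waters, nucleotides, ligands, ions).
    """
    name = resname.upper()
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name]
    parent = NONSTANDARD_PARENT.get(name)
    if parent is not None:
        return THREE_TO_ONE[parent]
    return None


# Canonical side-chain donor atom per residue type, used by the synthetic
# structure generator to plant a coordinating atom.  Only residues with a
# side-chain N/O/S can be planted as a ligand.
PLANT_DONOR_ATOM: dict[str, str] = {
    "C": "SG",
    "H": "NE2",
    "D": "OD2",
    "E": "OE2",
    "N": "OD1",
    "Q": "OE1",
    "S": "OG",
    "T": "OG1",
    "Y": "OH",
    "M": "SD",
    "K": "NZ",
    "R": "NH1",
    "W": "NE1",
}

DONOR_CAPABLE_RESIDUES: frozenset[str] = frozenset(PLANT_DONOR_ATOM)

# Elements that can donate a lone pair to a metal.
DONOR_ELEMENTS: frozenset[str] = frozenset({"N", "O", "S"})

# Backbone atoms that never count as donors (the amide nitrogen); the
# backbone carbonyl O does coordinate and is deliberately not listed.
NON_DONOR_BACKBONE_ATOMS: frozenset[str] = frozenset({"N"})
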