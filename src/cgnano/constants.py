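"""Physical constants, unit conversions, and per-residue tables.

Unit system: length Å, energy kcal/mol, mass amu, time fs, angles degrees
(radians only inside numerical kernels).
"""

# Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

# Converts kcal/mol/Å per amu into Å/fs^2 (acceleration).
ACC_CONVERSION = 4.184e-4

# Trans-peptide Calpha-Calpha virtual bond length, Å.
CA_CA_BOND = 3.8

# Mass carried by each backbone Calpha site: CalphaH plus the adjacent
# united peptide group share (N, H, C, O), amu.
CA_SITE_MASS = 56.0

# United peptide-group mass (C=O plus N-H), amu.  Peptide groups are not
# independent dynamic sites; this is used only for mass-weighted analyses.
PG_MASS = 43.0

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Side-chain masses (residue mass minus backbone), amu.  Glycine's side
# chain is a lone hydrogen; its dynamic site mass is floored at 12 amu for
# integration stability of the zero-length virtual bond.
SC_MASS = {
    "G": 12.0, "A": 15.0, "S": 31.0, "C": 47.0, "T": 45.0, "V": 43.0,
    "L": 57.0, "I": 57.0, "P": 42.0, "M": 75.0, "F": 91.0, "Y": 107.0,
    "W": 130.0, "D": 59.0, "E": 73.0, "N": 58.0, "Q": 72.0, "K": 72.0,
    "R": 100.0, "H": 81.0,
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}
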