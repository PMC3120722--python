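"""Physical constants for peptide mass arithmetic.

Monoisotopic amino-acid residue masses (Da), the mass of water and of the
proton, and the carbamidomethyl fixed-modification delta. Values follow the
IUPAC/Unimod standard tables (see docs/methods.md) and are kept to five
decimal places throughout.
"""

# Monoisotopic residue masses, Da (residue = amino acid minus water).
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Monoisotopic mass of H2O, Da.
WATER = 18.01056

#: Mass of a proton, Da.
PROTON = 1.00728

#: Carbamidomethylation of cysteine (iodoacetamide alkylation), Da.
CARBAMIDOMETHYL = 57.02146

#: The 20 standard residues.
STANDARD_RESIDUES = frozenset(RESIDUE_MASS)

#: Residues accepted in FASTA input ('X' = unknown; has no defined mass).
FASTA_RESIDUES = STANDARD_RESIDUES | {"X"}
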