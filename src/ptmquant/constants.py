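"""Monoisotopic mass constants.

The residue masses are the standard monoisotopic masses of the 20 canonical
amino-acid residues (i.e. the amino acid minus one water), frozen here to five
decimals so that every m/z the package prints is reproducible independent of
any external library version.  A dedicated test cross-checks the table against
an independent mass calculator.
"""

from __future__ import annotations

# Residue (not free amino acid) monoisotopic masses in Da.
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
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

#: Monoisotopic mass of water (Da); added once per peptide (terminal H and OH).
WATER_MONOISOTOPIC = 18.0105646863

#: Mass of the proton charge carrier (Da).  This is the bare proton, not the
#: hydrogen atom; the difference (one electron mass) is ~0.0005 Da.
PROTON_MASS = 1.007276466

#: The 20 canonical residue letters.
CANONICAL_RESIDUES = frozenset(MONOISOTOPIC_RESIDUE_MASSES)

#: Letters accepted in FASTA input ("X" marks an unknown residue and is
#: rejected by the mass calculator but tolerated by the sequence reader).
FASTA_RESIDUES = CANONICAL_RESIDUES | {"X"}
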