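"""Monoisotopic mass constants for peptide chemistry.

Residue masses are the standard monoisotopic masses of amino-acid
residues (i.e. the amino acid minus one water), in daltons, as tabulated
by IUPAC/Unimod. A peptide's neutral monoisotopic mass is the sum of its
residue masses plus one water, plus any modification deltas.
"""

from __future__ import annotations

PROTON_MASS: float = 1.00727646688
WATER_MASS: float = 18.0105646863
AMMONIA_MASS: float = 17.02654910

#: Monoisotopic residue masses (Da) for the 20 canonical amino acids.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146372,
    "A": 71.03711379,
    "S": 87.03202840,
    "P": 97.05276385,
    "V": 99.06841391,
    "T": 101.04767846,
    "C": 103.00918447,
    "L": 113.08406398,
    "I": 113.08406398,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857750,
    "K": 128.09496301,
    "E": 129.04259308,
    "M": 131.04048508,
    "H": 137.05891186,
    "F": 147.06841391,
    "R": 156.10111102,
    "Y": 163.06332853,
    "W": 186.07931295,
}

#: N-terminal Gln -> pyroglutamate: cyclization with loss of ammonia.
PYROGLU_FROM_GLN_DELTA: float = -17.0265491
#: C-terminal amidation: carboxyl -OH replaced by -NH2.
C_AMIDE_DELTA: float = -0.9840156
#: Carbamidomethylation of cysteine (iodoacetamide alkylation).
CARBAMIDOMETHYL_CYS_DELTA: float = +57.0214637

CANONICAL_RESIDUES: frozenset[str] = frozenset(MONOISOTOPIC_RESIDUE_MASS)
#: Ambiguity/rare letters that are tolerated in input sequences but
#: excluded from motif matches, candidates and mass computation.
AMBIGUOUS_RESIDUES: frozenset[str] = frozenset("BZXUO")
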