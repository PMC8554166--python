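"""Physicochemical and vocabulary constants used across the pipeline.

Free-amino-acid molecular weights (residue + water, g/mol), the essential
amino-acid set, the 10-compartment subcellular-localization vocabulary, and
the default pKa set for Henderson-Hasselbalch net-charge calculation.
"""

from __future__ import annotations

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_AA: str = "ACDEFGHIKLMNPQRSTVWY"

#: Average molecular weights of the free amino acids (g/mol), i.e. the
#: residue mass plus one water. Used when converting weight-based amino-acid
#: analysis (AAA) data to molar fractions.
AA_MW: dict[str, float] = {
    "G": 75.07,
    "A": 89.09,
    "S": 105.09,
    "P": 115.13,
    "V": 117.15,
    "T": 119.12,
    "C": 121.16,
    "L": 131.17,
    "I": 131.17,
    "N": 132.12,
    "D": 133.10,
    "Q": 146.15,
    "K": 146.19,
    "E": 147.13,
    "M": 149.21,
    "H": 155.15,
    "F": 165.19,
    "R": 174.20,
    "Y": 181.19,
    "W": 204.23,
}

# Acid hydrolysis deamidates Asn->Asp and Gln->Glu before quantification, so
# pooled Asx/Glx amounts are measured as the acid forms.
AA_MW_POOLED: dict[str, float] = {"Asx": AA_MW["D"], "Glx": AA_MW["E"]}

#: Weighted average amino-acid molecular weight including water (g/mol),
#: the single conversion constant used in weight -> molar conversion.
AVG_AA_MW: float = 128.0

#: Essential amino acids (adult requirement convention, FAO/WHO).
EAA: frozenset[str] = frozenset("HILKMFTWV")

#: Pooled-key definitions used when amide/acid forms are indistinguishable.
POOLED_KEYS: dict[str, tuple[str, str]] = {"Asx": ("D", "N"), "Glx": ("E", "Q")}

#: The 10-category subcellular localization vocabulary (DeepLoc-style).
COMPARTMENTS: tuple[str, ...] = (
    "Nucleus",
    "Cytoplasm",
    "Extracellular",
    "Mitochondrion",
    "Cell_membrane",
    "Endoplasmic_reticulum",
    "Plastid",
    "Golgi_apparatus",
    "Lysosome/Vacuole",
    "Peroxisome",
)

UNKNOWN_COMPARTMENT: str = "unknown"

#: Default pKa set for net-charge calculation at a given pH.
#: Keys: "n_term", "c_term" and the ionizable side chains.
DEFAULT_PKA: dict[str, float] = {
    "n_term": 9.0,
    "c_term": 3.55,
    "D": 3.65,
    "E": 4.25,
    "C": 8.3,
    "Y": 10.1,
    "H": 6.0,
    "K": 10.5,
    "R": 12.5,
}

#: Background amino-acid frequencies used by the synthetic proteome
#: generator (approximate average composition of a eukaryotic proteome).
BACKGROUND_AA_FREQ: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}
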