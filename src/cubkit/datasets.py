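"""Published reference data for *Bombyx mori* codon usage.

Pooled codon counts and RSCU values of the putatively highly- and
lowly-expressed gene pools of *B. mori* (the axis-1 extremes of a
correspondence analysis of RSCU over 1,097 curated RefSeq coding
sequences, the lower-ENc tail assigned as highly expressed), together
with the codons reported as translationally optimal (p < 0.01, all G/C
ending). These printed pool counts are self-consistent with pooled RSCU
computation and serve as the package's numeric ground truth for the
optimal-codon procedure.

Codons are keyed as DNA; ``rna()`` from :mod:`cubkit.genetic_code`
converts for display.
"""

from __future__ import annotations

from .codon_metrics import CodonCountTable

# codon -> (rscu_high, n_high, rscu_low, n_low)
BMORI_POOLS: dict[str, tuple[float, int, float, int]] = {
    # Ala
    "GCT": (0.64, 288, 1.66, 315),
    "GCC": (1.80, 818, 0.46, 88),
    "GCA": (0.29, 133, 1.65, 313),
    "GCG": (1.27, 575, 0.23, 43),
    # Arg
    "CGT": (0.63, 126, 0.76, 81),
    "CGC": (2.49, 495, 0.21, 22),
    "CGA": (0.37, 74, 0.87, 93),
    "CGG": (1.04, 207, 0.23, 24),
    "AGA": (0.61, 121, 3.05, 325),
    "AGG": (0.86, 172, 0.89, 95),
    # Asn
    "AAT": (0.34, 130, 1.39, 549),
    "AAC": (1.66, 631, 0.61, 239),
    # Asp
    "GAT": (0.38, 226, 1.46, 587),
    "GAC": (1.62, 958, 0.54, 217),
    # Cys
    "TGT": (0.35, 64, 1.50, 179),
    "TGC": (1.65, 302, 0.50, 60),
    # Gln
    "CAA": (0.44, 174, 1.43, 370),
    "CAG": (1.56, 615, 0.57, 146),
    # Glu
    "GAA": (0.57, 414, 1.59, 769),
    "GAG": (1.43, 1036, 0.41, 197),
    # Gly
    "GGT": (0.65, 240, 1.49, 291),
    "GGC": (1.91, 703, 0.58, 113),
    "GGA": (0.75, 277, 1.55, 303),
    "GGG": (0.69, 254, 0.39, 76),
    # His
    "CAT": (0.38, 97, 1.44, 196),
    "CAC": (1.62, 416, 0.56, 76),
    # Ile
    "ATT": (0.34, 99, 1.37, 407),
    "ATC": (2.23, 652, 0.39, 115),
    "ATA": (0.43, 126, 1.24, 368),
    # Leu
    "TTA": (0.17, 49, 2.18, 442),
    "TTG": (0.61, 179, 1.30, 264),
    "CTT": (0.30, 88, 0.89, 181),
    "CTC": (2.05, 602, 0.35, 71),
    "CTA": (0.27, 78, 0.75, 152),
    "CTG": (2.60, 764, 0.53, 108),
    # Lys
    "AAA": (0.48, 278, 1.55, 924),
    "AAG": (1.52, 870, 0.45, 269),
    # Met
    "ATG": (1.00, 507, 1.00, 359),
    # Phe
    "TTT": (0.24, 91, 1.48, 396),
    "TTC": (1.76, 680, 0.52, 140),
    # Pro
    "CCT": (0.48, 122, 1.46, 204),
    "CCC": (1.65, 418, 0.35, 49),
    "CCA": (0.36, 91, 1.87, 261),
    "CCG": (1.50, 380, 0.32, 45),
    # Ser
    "TCT": (0.71, 153, 1.49, 233),
    "TCC": (1.71, 366, 0.44, 69),
    "TCA": (0.42, 90, 1.77, 276),
    "TCG": (1.56, 335, 0.34, 53),
    "AGT": (0.34, 72, 1.40, 219),
    "AGC": (1.26, 271, 0.55, 86),
    # Thr
    "ACT": (0.57, 146, 1.49, 275),
    "ACC": (1.68, 433, 0.43, 79),
    "ACA": (0.43, 110, 1.85, 343),
    "ACG": (1.32, 339, 0.23, 43),
    # Trp
    "TGG": (1.00, 219, 1.00, 157),
    # Tyr
    "TAT": (0.29, 100, 1.40, 322),
    "TAC": (1.71, 595, 0.60, 138),
    # Val
    "GTT": (0.41, 144, 1.59, 363),
    "GTC": (1.32, 469, 0.48, 109),
    "GTA": (0.36, 126, 1.26, 289),
    "GTG": (1.91, 678, 0.67, 153),
    # stop
    "TGA": (0.94, 17, 0.61, 11),
    "TAA": (1.50, 27, 1.83, 33),
    "TAG": (0.56, 10, 0.56, 10),
}

#: the 27 codons reported as optimal (all G/C-ending)
BMORI_OPTIMAL_CODONS: frozenset[str] = frozenset(
    {
        "GCC", "GCG", "CGC", "CGG", "AAC", "GAC", "TGC", "CAG", "GAG",
        "GGC", "GGG", "CAC", "ATC", "CTC", "CTG", "AAG", "TTC", "CCC",
        "CCG", "TCC", "TCG", "AGC", "ACC", "ACG", "TAC", "GTC", "GTG",
    }
)


def bmori_high_pool() -> CodonCountTable:
    """Pooled codon counts of the putatively highly expressed gene pool."""
    return CodonCountTable({c: v[1] for c, v in BMORI_POOLS.items()})


def bmori_low_pool() -> CodonCountTable:
    """Pooled codon counts of the lowly expressed gene pool."""
    return CodonCountTable({c: v[3] for c, v in BMORI_POOLS.items()})


def bmori_rscu_high() -> dict[str, float]:
    """Published pooled RSCU values, high pool (2-decimal precision)."""
    return {c: v[0] for c, v in BMORI_POOLS.items()}


def bmori_rscu_low() -> dict[str, float]:
    """Published pooled RSCU values, low pool (2-decimal precision)."""
    return {c: v[2] for c, v in BMORI_POOLS.items()}
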