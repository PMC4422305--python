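"""Standard genetic code tables and derived constants.

Everything here is derived once, at import time, from the NCBI standard code
(translation table 1) as shipped with Biopython, so the synonymous-family
structure (nine 2-fold families, Ile as the sole 3-fold family, Leu/Ser/Arg
as 6-fold families) is never hand-typed.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))  # TAA, TAG, TGA
START_CODON = "ATG"

ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)
SENSE_CODONS: tuple[str, ...] = tuple(c for c in ALL_CODONS if c in CODON_TO_AA)

#: amino acid -> sorted tuple of its codons
SYN_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    SYN_FAMILIES.setdefault(_aa, ())
SYN_FAMILIES = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in SYN_FAMILIES
}

#: amino acid -> number of synonymous codons (degeneracy)
DEGENERACY: dict[str, int] = {aa: len(cods) for aa, cods in SYN_FAMILIES.items()}

#: amino acids with more than one codon, i.e. those carrying synonymous choice
DEGENERATE_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, k in DEGENERACY.items() if k > 1)
)
SINGLE_CODON_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, k in DEGENERACY.items() if k == 1)
)  # M, W

#: degeneracy class -> amino acids in it (k in {2, 3, 4, 6} for the standard code)
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa in DEGENERATE_AAS:
    DEGENERACY_CLASSES.setdefault(DEGENERACY[_aa], ())
DEGENERACY_CLASSES = {
    k: tuple(sorted(aa for aa in DEGENERATE_AAS if DEGENERACY[aa] == k))
    for k in sorted(DEGENERACY_CLASSES)
}

#: codons belonging to synonymous families (Met, Trp excluded): the 59 columns
#: of the RSCU matrix, ordered by amino acid then alphabetically within family.
CODONS_59: tuple[str, ...] = tuple(
    c for aa in DEGENERATE_AAS for c in SYN_FAMILIES[aa]
)

AROMATIC_AAS: frozenset[str] = frozenset("FWY")

AA_ORDER: tuple[str, ...] = tuple(sorted(SYN_FAMILIES))  # 20 amino acids


def dna(codon: str) -> str:
    """Normalize a codon to the uppercase DNA alphabet (U -> T)."""
    return codon.upper().replace("U", "T")


def rna(codon: str) -> str:
    """Render a DNA codon in the RNA alphabet used in printed tables."""
    return codon.upper().replace("T", "U")
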