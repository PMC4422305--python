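"""Per-gene and pooled codon-usage indices.

Implements the classical descriptive toolkit of codon-usage analysis:

* codon counting (terminal stop excluded, GenBank CDS convention),
* RSCU — relative synonymous codon usage, the observed codon count divided
  by its expectation under uniform synonymous usage (family values sum to
  the family's degeneracy),
* positional G+C content (GC1/GC2/GC3, their mean, and GC12),
* silent-site base composition (A3s/T3s/C3s/G3s, GC3s) over codons that
  belong to synonymous families (Met, Trp and stops excluded),
* Wright's effective number of codons (ENc; 20 = one codon per amino acid,
  61 = no bias) and the mutation-only expectation ENc(S) driven by GC3s,
* the codon adaptation index (CAI) against a highly-expressed reference
  set, as the geometric mean of relative adaptiveness values,
* GRAVY (mean Kyte–Doolittle hydropathy) and aromaticity of the conceptual
  translation.

Undefined quantities (e.g. ENc for a gene with no usable families) are
returned as NaN rather than raised, so a metrics table can always be built.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cds_io import CodingSequence
from .genetic_code import (
    ALL_CODONS,
    AROMATIC_AAS,
    CODON_TO_AA,
    DEGENERACY,
    DEGENERACY_CLASSES,
    DEGENERATE_AAS,
    KYTE_DOOLITTLE,
    SENSE_CODONS,
    STOP_CODONS,
    SYN_FAMILIES,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CodonCountTable",
    "CAIReferenceWeights",
    "GeneMetrics",
    "count_codons",
    "rscu",
    "gc_partitions",
    "silent_composition",
    "enc",
    "expected_enc",
    "cai_weights",
    "cai",
    "gravy",
    "aromo",
    "compute_gene_metrics",
    "metrics_table",
    "write_metrics_tsv",
    "write_codon_usage_tsv",
]


class CodonCountTable:
    """Counts for all 64 codons, for one gene or a pooled gene set."""

    __slots__ = ("counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        self.counts: dict[str, int] = {c: 0 for c in ALL_CODONS}
        if counts:
            for codon, n in counts.items():
                codon = codon.upper().replace("U", "T")
                if codon not in self.counts:
                    raise ValueError(f"not a codon: {codon!r}")
                if n < 0:
                    raise ValueError(f"negative count for {codon}")
                self.counts[codon] += int(n)

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts[codon.upper().replace("U", "T")]

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {c: self.counts[c] + other.counts[c] for c in ALL_CODONS}
        return CodonCountTable(merged)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CodonCountTable) and self.counts == other.counts

    def __repr__(self) -> str:
        nz = {c: n for c, n in self.counts.items() if n}
        return f"CodonCountTable({nz!r})"

    def family_total(self, aa: str) -> int:
        return sum(self.counts[c] for c in SYN_FAMILIES[aa])

    def aa_counts(self) -> dict[str, int]:
        """Amino-acid counts of the conceptual translation (stops excluded)."""
        out = {aa: 0 for aa in SYN_FAMILIES}
        for codon, n in self.counts.items():
            aa = CODON_TO_AA.get(codon)
            if aa is not None:
                out[aa] += n
        return out


def count_codons(
    seq_or_pool: CodingSequence | Iterable[CodingSequence],
) -> CodonCountTable:
    """Count in-frame codons, excluding each gene's terminal stop codon.

    Accepts a single QC-passed sequence or an iterable (pooling sums the
    per-gene tables). Raises on sequences whose length is not a multiple
    of three.
    """
    if isinstance(seq_or_pool, CodingSequence):
        seqs: Iterable[CodingSequence] = [seq_or_pool]
    else:
        seqs = seq_or_pool
    counts = {c: 0 for c in ALL_CODONS}
    for s in seqs:
        if s.length_nt % 3 != 0:
            raise ValueError(f"{s.id}: length {s.length_nt} not a multiple of 3")
        codons = s.codons()
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        for c in codons:
            try:
                counts[c] += 1
            except KeyError:
                raise ValueError(f"{s.id}: non-ACGT codon {c!r}") from None
    return CodonCountTable(counts)


def rscu(counts: CodonCountTable, include_stops: bool = False) -> dict[str, float]:
    """Relative synonymous codon usage for every sense codon.

    For codon ``c`` in a k-fold family with family total ``T``:
    ``RSCU(c) = k * n_c / T``. Families with ``T == 0`` yield NaN. Met and
    Trp get RSCU 1.0 when present (NaN when absent). With
    ``include_stops=True`` the three stop codons are treated as one 3-fold
    family.
    """
    out: dict[str, float] = {}
    families: list[tuple[int, tuple[str, ...]]] = [
        (DEGENERACY[aa], SYN_FAMILIES[aa]) for aa in SYN_FAMILIES
    ]
    if include_stops:
        families.append((len(STOP_CODONS), STOP_CODONS))
    for k, codons in families:
        total = sum(counts.counts[c] for c in codons)
        for c in codons:
            out[c] = k * counts.counts[c] / total if total > 0 else math.nan
    return out


def gc_partitions(counts: CodonCountTable) -> tuple[float, float, float, float, float]:
    """G+C fractions by codon position: returns (gc, gc1, gc2, gc3, gc12).

    ``gc`` is the overall fraction (the mean of the three positions),
    ``gc12`` the mean of positions 1 and 2. Raises on an empty table.
    """
    n = counts.n_codons
    if n == 0:
        raise ValueError("empty codon table: GC partitions undefined")
    gc_pos = [0, 0, 0]
    for codon, cnt in counts.counts.items():
        if cnt == 0:
            continue
        for i, base in enumerate(codon):
            if base in "GC":
                gc_pos[i] += cnt
    gc1, gc2, gc3 = (g / n for g in gc_pos)
    return ((gc1 + gc2 + gc3) / 3, gc1, gc2, gc3, (gc1 + gc2) / 2)


def silent_composition(
    counts: CodonCountTable, method: str = "simple"
) -> tuple[float, float, float, float, float]:
    """Base composition at synonymous third positions: (gc3s, a3s, t3s, c3s, g3s).

    ``method="simple"`` (default, documented): over codons belonging to
    synonymous families only (Met, Trp, stops excluded), ``x3s`` is the
    fraction of such codons with base ``x`` at position 3; ``gc3s = c3s+g3s``.

    ``method="opportunity"``: codonW-style per-base denominators — for base
    ``x``, only codons from families that offer an ``x``-ending synonym
    enter the denominator. ``gc3s`` is unchanged by the switch in practice
    for families offering all four bases but can differ for restricted
    families; the simple definition is the default throughout.

    Raises if no synonymous-family codons are present.
    """
    if method not in ("simple", "opportunity"):
        raise ValueError(f"unknown method {method!r}")
    base_num = {b: 0 for b in "ACGT"}
    base_den = {b: 0 for b in "ACGT"}
    total = 0
    for aa in DEGENERATE_AAS:
        fam = SYN_FAMILIES[aa]
        fam_total = sum(counts.counts[c] for c in fam)
        fam_bases = {c[2] for c in fam}
        total += fam_total
        for c in fam:
            base_num[c[2]] += counts.counts[c]
        for b in fam_bases:
            base_den[b] += fam_total
    if total == 0:
        raise ValueError("no synonymous-family codons: silent composition undefined")
    if method == "simple":
        a3s, c3s, g3s, t3s = (base_num[b] / total for b in "ACGT")
    else:
        a3s, c3s, g3s, t3s = (
            base_num[b] / base_den[b] if base_den[b] else math.nan for b in "ACGT"
        )
    gc3s = (base_num["C"] + base_num["G"]) / total
    return gc3s, a3s, t3s, c3s, g3s


def enc(counts: CodonCountTable) -> float:
    """Wright's effective number of codons.

    For each amino acid of degeneracy k > 1 with n >= 2 observed codons,
    the codon homozygosity is ``F = (n * sum(p_i^2) - 1) / (n - 1)``.
    F values of exactly 0 are excluded from their degeneracy-class average
    (codonW convention). ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, capped at 61.
    A missing 3-fold average (Ile absent or F = 0) is imputed as
    ``(F2 + F4) / 2``; any other missing class makes ENc undefined (NaN).
    """
    class_f: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = []
        for aa in aas:
            fam = SYN_FAMILIES[aa]
            n = sum(counts.counts[c] for c in fam)
            if n < 2:
                continue
            sum_p2 = sum((counts.counts[c] / n) ** 2 for c in fam)
            f = (n * sum_p2 - 1) / (n - 1)
            if f > 0:
                fs.append(f)
        if fs:
            class_f[k] = sum(fs) / len(fs)
    if 3 not in class_f and 2 in class_f and 4 in class_f:
        class_f[3] = (class_f[2] + class_f[4]) / 2
    n_families = {k: len(aas) for k, aas in DEGENERACY_CLASSES.items()}
    if set(class_f) != set(n_families):
        return math.nan
    value = 2.0 + sum(n_families[k] / class_f[k] for k in n_families)
    return min(value, 61.0)


def expected_enc(gc3s: float) -> float:
    """Mutation-only ENc expectation from silent-site G+C content.

    ``ENc(S) = 2 + S + 29 / (S^2 + (1-S)^2)`` with ``S = GC3s``. Genes whose
    codon choice is shaped only by a G+C mutation bias fall on this curve;
    genes under additional constraints (e.g. translational selection) fall
    below it.
    """
    s = float(gc3s)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s must be in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


@dataclass(frozen=True)
class CAIReferenceWeights:
    """Relative adaptiveness w of each sense codon, from a reference gene set.

    Within each synonymous family, w = RSCU / max RSCU, so the family's most
    used codon has w = 1. Codons unseen in the reference receive a small
    floor weight instead of 0 so log-weights stay finite.
    """

    w: Mapping[str, float]
    source_ids: tuple[str, ...] = field(default_factory=tuple)


def cai_weights(
    reference: CodonCountTable | Iterable[CodonCountTable],
    floor: float = 0.01,
    source_ids: Sequence[str] = (),
) -> CAIReferenceWeights:
    """Relative adaptiveness weights from a pooled reference gene set."""
    if isinstance(reference, CodonCountTable):
        pooled = reference
    else:
        pooled = CodonCountTable()
        n_tables = 0
        for t in reference:
            pooled = pooled + t
            n_tables += 1
        if n_tables == 0:
            raise ValueError("empty CAI reference pool")
    ref_rscu = rscu(pooled)
    w: dict[str, float] = {}
    for aa in DEGENERATE_AAS:
        fam = SYN_FAMILIES[aa]
        fam_max = max(ref_rscu[c] for c in fam)
        if math.isnan(fam_max) or fam_max == 0:
            logger.warning("CAI reference lacks any %s codon; floor weights used", aa)
            for c in fam:
                w[c] = floor
            continue
        for c in fam:
            val = ref_rscu[c] / fam_max
            w[c] = val if val > 0 else floor
    return CAIReferenceWeights(w=w, source_ids=tuple(source_ids))


def cai(counts: CodonCountTable, weights: CAIReferenceWeights) -> float:
    """Codon adaptation index: geometric mean of w over the gene's codons.

    Met, Trp and stop codons are excluded. Returns NaN if the gene has no
    eligible codons.
    """
    log_sum = 0.0
    n = 0
    for aa in DEGENERATE_AAS:
        for c in SYN_FAMILIES[aa]:
            cnt = counts.counts[c]
            if cnt:
                log_sum += cnt * math.log(weights.w[c])
                n += cnt
    if n == 0:
        return math.nan
    return math.exp(log_sum / n)


def gravy(counts: CodonCountTable) -> float:
    """Mean Kyte–Doolittle hydropathy of the conceptual translation."""
    total = 0
    acc = 0.0
    for aa, n in counts.aa_counts().items():
        acc += n * KYTE_DOOLITTLE[aa]
        total += n
    if total == 0:
        return math.nan
    return acc / total


def aromo(counts: CodonCountTable) -> float:
    """Fraction of aromatic residues (Phe, Tyr, Trp) in the translation."""
    aa_counts = counts.aa_counts()
    total = sum(aa_counts.values())
    if total == 0:
        return math.nan
    return sum(aa_counts[aa] for aa in AROMATIC_AAS) / total


@dataclass
class GeneMetrics:
    """The full per-gene index record.

    Fractions are stored in [0, 1] (reports render them as percentages).
    ``counts`` retains the gene's codon table so downstream matrices
    (RSCU, amino-acid usage) can be built without re-reading sequences.
    """

    id: str
    length_nt: int
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float
    a3s: float
    t3s: float
    c3s: float
    g3s: float
    enc: float
    cai: float
    gravy: float
    aromo: float
    rscu: dict[str, float]
    counts: CodonCountTable


def compute_gene_metrics(
    seq: CodingSequence,
    weights: CAIReferenceWeights | None = None,
    silent_method: str = "simple",
) -> GeneMetrics:
    """Compute every codon-usage index for one QC-passed gene."""
    counts = count_codons(seq)
    gc, gc1, gc2, gc3, gc12 = gc_partitions(counts)
    try:
        gc3s, a3s, t3s, c3s, g3s = silent_composition(counts, method=silent_method)
    except ValueError:
        gc3s = a3s = t3s = c3s = g3s = math.nan
    return GeneMetrics(
        id=seq.id,
        length_nt=seq.length_nt,
        gc=gc,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc12=gc12,
        gc3s=gc3s,
        a3s=a3s,
        t3s=t3s,
        c3s=c3s,
        g3s=g3s,
        enc=enc(counts),
        cai=cai(counts, weights) if weights is not None else math.nan,
        gravy=gravy(counts),
        aromo=aromo(counts),
        rscu=rscu(counts),
        counts=counts,
    )


_METRIC_COLUMNS = (
    "length_nt",
    "gc",
    "gc1",
    "gc2",
    "gc3",
    "gc12",
    "gc3s",
    "a3s",
    "t3s",
    "c3s",
    "g3s",
    "enc",
    "cai",
    "gravy",
    "aromo",
)


def metrics_table(genes: Sequence[GeneMetrics]) -> pd.DataFrame:
    """Assemble per-gene metrics into a DataFrame indexed by gene id."""
    rows = {g.id: [getattr(g, c) for c in _METRIC_COLUMNS] for g in genes}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(_METRIC_COLUMNS))
    df.index.name = "id"
    return df


def write_metrics_tsv(genes: Sequence[GeneMetrics], path: str | Path) -> None:
    """Per-gene metrics TSV; fractions as percentages to 2 decimals."""
    df = metrics_table(genes).copy()
    pct_cols = ["gc", "gc1", "gc2", "gc3", "gc12", "gc3s", "a3s", "t3s", "c3s", "g3s"]
    df[pct_cols] = (df[pct_cols] * 100).round(2)
    df[["enc", "cai", "gravy", "aromo"]] = df[["enc", "cai", "gravy", "aromo"]].round(4)
    df.to_csv(path, sep="\t")


def write_codon_usage_tsv(pooled: CodonCountTable, path: str | Path) -> None:
    """Pooled codon-usage TSV: amino acid, codon (RNA), count, RSCU."""
    vals = rscu(pooled, include_stops=True)
    with open(path, "w") as fh:
        fh.write("amino_acid\tcodon\tcount\trscu\n")
        for codon in sorted(
            vals, key=lambda c: (CODON_TO_AA.get(c, "~stop"), c)
        ):
            aa = CODON_TO_AA.get(codon, "*")
            r = vals[codon]
            fh.write(
                f"{aa}\t{codon.replace('T', 'U')}\t{pooled.counts[codon]}\t"
                f"{'' if math.isnan(r) else f'{r:.2f}'}\n"
            )
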