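"""Synthetic coding-sequence generator with controlled codon-usage structure.

Emulates the statistical shape of a curated CDS collection: every gene is
ATG + sampled sense codons + one stop codon, so the whole set passes QC by
construction. Codon choice is controlled per amino-acid family, either
directly (``codon_prefs``) or through a target silent-site G+C content
(``gc3_target``), which splits each family's probability mass between its
G/C-ending and A/T-ending codons. A configurable fraction of genes forms a
"highly expressed" class in which a planted set of optimal codons is
up-weighted by an enrichment factor — the ground truth against which
optimal-codon recovery is measured.

Reproducibility: one integer seed; each gene draws from its own counter-
derived substream, so changing ``n_genes`` never reshuffles earlier genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cds_io import CodingSequence
from .genetic_code import (
    DEGENERACY,
    DEGENERATE_AAS,
    STOP_CODONS,
    SYN_FAMILIES,
)

__all__ = [
    "SyntheticConfig",
    "default_aa_composition",
    "uniform_codon_prefs",
    "gc3_targeted_prefs",
    "gc_ending_codons",
    "generate",
]


def default_aa_composition() -> dict[str, float]:
    """Uniform over the 18 degenerate amino acids, Met/Trp at low weight.

    Every ENc degeneracy class is therefore populated in genes of realistic
    length, while single-codon amino acids stay present but rare (weight
    0.2 relative to a degenerate amino acid).
    """
    weights = {aa: 1.0 for aa in DEGENERATE_AAS}
    weights.update({"M": 0.2, "W": 0.2})
    total = sum(weights.values())
    return {aa: w / total for aa, w in weights.items()}


def uniform_codon_prefs() -> dict[str, dict[str, float]]:
    """Uniform within-family codon sampling (the no-bias limit)."""
    return {
        aa: {c: 1.0 / len(cods) for c in cods} for aa, cods in SYN_FAMILIES.items()
    }


def gc_ending_codons() -> frozenset[str]:
    """All codons of degenerate families ending in G or C."""
    return frozenset(
        c for aa in DEGENERATE_AAS for c in SYN_FAMILIES[aa] if c[2] in "GC"
    )


def gc3_targeted_prefs(gc3_target: float) -> dict[str, dict[str, float]]:
    """Within-family preferences realizing a target silent-site G+C content.

    In each family the G/C-ending codons share total weight ``gc3_target``
    evenly and the A/T-ending codons share ``1 - gc3_target``; families
    offering only one class renormalize to it.
    """
    if not 0.0 <= gc3_target <= 1.0:
        raise ValueError(f"gc3_target must be in [0, 1], got {gc3_target}")
    prefs: dict[str, dict[str, float]] = {}
    for aa, cods in SYN_FAMILIES.items():
        gc_c = [c for c in cods if c[2] in "GC"]
        at_c = [c for c in cods if c[2] in "AT"]
        w = {}
        for c in gc_c:
            w[c] = gc3_target / len(gc_c)
        for c in at_c:
            w[c] = (1.0 - gc3_target) / len(at_c)
        total = sum(w.values())
        if total == 0:  # target 0 with a GC-only family (or 1 with AT-only)
            w = {c: 1.0 / len(cods) for c in cods}
            total = 1.0
        prefs[aa] = {c: v / total for c, v in w.items()}
    return prefs


@dataclass
class SyntheticConfig:
    """Study-condition parameters for one synthetic CDS set.

    ``length_range_codons`` bounds the total codon count per gene
    (start and stop included); the default range keeps every gene at or
    above the 300 nt QC threshold and matches typical CDS lengths.
    """

    n_genes: int = 1000
    length_range_codons: tuple[int, int] = (100, 500)
    aa_composition: Mapping[str, float] = field(default_factory=default_aa_composition)
    codon_prefs: Mapping[str, Mapping[str, float]] | None = None
    gc3_target: float | None = None
    high_expr_fraction: float = 0.0
    planted_optimal: frozenset[str] = field(default_factory=gc_ending_codons)
    enrichment_factor: float = 1.0
    seed: int = 0

    def resolved_prefs(self) -> dict[str, dict[str, float]]:
        if self.codon_prefs is not None and self.gc3_target is not None:
            raise ValueError("give codon_prefs or gc3_target, not both")
        if self.gc3_target is not None:
            return gc3_targeted_prefs(self.gc3_target)
        if self.codon_prefs is None:
            return uniform_codon_prefs()
        return {aa: dict(cods) for aa, cods in self.codon_prefs.items()}

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.length_range_codons
        if lo < 100 or hi < lo:
            raise ValueError("length range must satisfy 100 <= min <= max")
        if not 0.0 <= self.high_expr_fraction <= 1.0:
            raise ValueError("high_expr_fraction must be in [0, 1]")
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be positive")
        if abs(sum(self.aa_composition.values()) - 1.0) > 1e-9:
            raise ValueError("aa_composition must sum to 1")
        prefs = self.resolved_prefs()
        missing = set(self.aa_composition) - set(prefs)
        if missing:
            raise ValueError(f"no codon preferences for: {sorted(missing)}")
        for aa, cods in prefs.items():
            if aa not in SYN_FAMILIES:
                raise ValueError(f"unknown amino acid {aa!r}")
            total = sum(cods.values())
            if total <= 0 or abs(total - 1.0) > 1e-9:
                raise ValueError(f"codon preferences for {aa} must sum to 1")
            if set(cods) - set(SYN_FAMILIES[aa]):
                raise ValueError(f"codons outside family {aa}: {cods}")


def _enriched(
    prefs: dict[str, dict[str, float]],
    planted: frozenset[str],
    factor: float,
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for aa, cods in prefs.items():
        w = {c: p * (factor if c in planted else 1.0) for c, p in cods.items()}
        total = sum(w.values())
        out[aa] = {c: v / total for c, v in w.items()}
    return out


def generate(
    config: SyntheticConfig,
) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Generate a synthetic CDS set and its ground-truth table.

    Returns the sequences (all QC-valid by construction) and a truth
    DataFrame with columns id, expr_class, length_nt, gc3_target.
    """
    config.validate()
    base_prefs = config.resolved_prefs()
    high_prefs = _enriched(
        base_prefs, config.planted_optimal, config.enrichment_factor
    )
    aas = sorted(config.aa_composition)
    aa_p = np.array([config.aa_composition[a] for a in aas])
    n_high = round(config.high_expr_fraction * config.n_genes)
    lo, hi = config.length_range_codons
    width = len(str(config.n_genes))
    seqs: list[CodingSequence] = []
    truth_rows = []
    for i in range(config.n_genes):
        rng = np.random.default_rng([config.seed, i])
        is_high = i < n_high
        prefs = high_prefs if is_high else base_prefs
        n_codons = int(rng.integers(lo, hi + 1))
        aa_seq = rng.choice(aas, size=n_codons - 2, p=aa_p)
        codons = np.empty(n_codons - 2, dtype=object)
        for aa in aas:  # fixed iteration order keeps the stream deterministic
            pos = np.flatnonzero(aa_seq == aa)
            if pos.size == 0:
                continue
            fam = sorted(prefs[aa])
            fam_p = np.array([prefs[aa][c] for c in fam])
            codons[pos] = rng.choice(fam, size=pos.size, p=fam_p)
        stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
        seq = "ATG" + "".join(codons) + stop
        gene_id = f"g{i + 1:0{width}d}"
        seqs.append(CodingSequence(id=gene_id, seq=seq))
        truth_rows.append(
            {
                "id": gene_id,
                "expr_class": "high" if is_high else "background",
                "length_nt": len(seq),
                "gc3_target": (
                    config.gc3_target if config.gc3_target is not None else math.nan
                ),
            }
        )
    return seqs, pd.DataFrame(truth_rows)
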