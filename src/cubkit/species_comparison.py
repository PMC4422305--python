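"""Cross-species codon-preference comparison.

Reads reference codon-usage tables in the Codon Usage Database (Kazusa)
text layout — whitespace-separated ``triplet per-1000 (count)`` fields —
and compares a pooled codon count table against them. Own counts are
converted to per-1000 frequencies over all counted codons (stop codons
included in the normalization, as in the Kazusa tables). Codons whose
frequency ratio exceeds 2 or falls below 0.5 (strict inequalities) are
"indicative": their usage differs markedly between the two species.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .codon_metrics import CodonCountTable
from .genetic_code import ALL_CODONS, CODON_TO_AA, dna, rna

__all__ = [
    "ReferenceUsageTable",
    "parse_kazusa",
    "read_kazusa",
    "frequency_ratio",
    "indicative_codons",
    "comparison_table",
]

_ENTRY = re.compile(r"([ACGUTacgut]{3})\s+(\d+(?:\.\d+)?)\s*\(\s*(\d+)\s*\)")


@dataclass(frozen=True)
class ReferenceUsageTable:
    """One organism's codon usage as per-1000 frequencies (DNA-keyed)."""

    organism: str
    freq_per_1000: Mapping[str, float]
    counts: Mapping[str, int] = field(default_factory=dict)


def parse_kazusa(text: str, organism: str = "") -> ReferenceUsageTable:
    """Parse a Kazusa-format codon usage table.

    All 64 codons must be present; duplicates and malformed entries raise
    with the offending codon or line named. The per-1000 frequencies must
    sum to 1000 +/- 1.
    """
    freq: dict[str, float] = {}
    counts: dict[str, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        matches = list(_ENTRY.finditer(stripped))
        residue = _ENTRY.sub("", stripped).strip()
        if not matches or residue:
            raise ValueError(f"malformed codon-usage line {lineno}: {line!r}")
        for m in matches:
            codon = dna(m.group(1))
            if codon in freq:
                raise ValueError(f"duplicate codon {rna(codon)} (line {lineno})")
            freq[codon] = float(m.group(2))
            counts[codon] = int(m.group(3))
    missing = sorted(set(ALL_CODONS) - set(freq))
    if missing:
        raise ValueError(f"incomplete table, missing: {', '.join(map(rna, missing))}")
    total = sum(freq.values())
    if abs(total - 1000.0) > 1.0:
        raise ValueError(f"per-1000 frequencies sum to {total:.3f}, not 1000±1")
    return ReferenceUsageTable(organism=organism, freq_per_1000=freq, counts=counts)


def read_kazusa(path: str | Path, organism: str | None = None) -> ReferenceUsageTable:
    """Read a Kazusa-format table from a file (organism defaults to the stem)."""
    path = Path(path)
    return parse_kazusa(path.read_text(), organism=organism or path.stem)


def own_frequencies_per_1000(own: CodonCountTable) -> dict[str, float]:
    """Convert pooled counts to per-1000 frequencies over all counted codons."""
    n = own.n_codons
    if n == 0:
        raise ValueError("empty codon pool")
    return {c: 1000.0 * own.counts[c] / n for c in ALL_CODONS}


def frequency_ratio(
    own: CodonCountTable, ref: ReferenceUsageTable, method: str = "per1000"
) -> dict[str, float]:
    """Per-codon usage ratio own/reference.

    ``method="per1000"`` (default) compares per-1000 frequencies over all
    codons; ``method="family"`` compares within-family relative synonymous
    frequencies instead (stops and single-codon families excluded from the
    alternative only in the sense that their family share is trivially 1).
    Reference frequency 0 gives NaN (flagged undefined), never infinity.
    """
    if method not in ("per1000", "family"):
        raise ValueError(f"unknown method {method!r}")
    if method == "per1000":
        own_f = own_frequencies_per_1000(own)
        ref_f = dict(ref.freq_per_1000)
    else:
        own_f, ref_f = {}, {}
        fams: dict[str, list[str]] = {}
        for c in ALL_CODONS:
            fams.setdefault(CODON_TO_AA.get(c, "*"), []).append(c)
        for fam in fams.values():
            own_tot = sum(own.counts[c] for c in fam)
            ref_tot = sum(ref.freq_per_1000[c] for c in fam)
            for c in fam:
                own_f[c] = own.counts[c] / own_tot if own_tot else math.nan
                ref_f[c] = ref.freq_per_1000[c] / ref_tot if ref_tot else math.nan
    return {
        c: (own_f[c] / ref_f[c]) if ref_f.get(c) else math.nan for c in ALL_CODONS
    }


def indicative_codons(
    ratios: Mapping[str, float], hi: float = 2.0, lo: float = 0.5
) -> frozenset[str]:
    """Codons with ratio strictly above ``hi`` or strictly below ``lo``.

    Undefined (NaN) ratios are excluded.
    """
    return frozenset(
        c
        for c, r in ratios.items()
        if not math.isnan(r) and (r > hi or r < lo)
    )


def comparison_table(
    own: CodonCountTable, ref: ReferenceUsageTable, hi: float = 2.0, lo: float = 0.5
) -> pd.DataFrame:
    """Per-codon comparison report (codons rendered in the RNA alphabet)."""
    ratios = frequency_ratio(own, ref)
    own_f = own_frequencies_per_1000(own)
    indic = indicative_codons(ratios, hi=hi, lo=lo)
    rows = [
        {
            "codon": rna(c),
            "amino_acid": CODON_TO_AA.get(c, "*"),
            "own_freq": round(own_f[c], 4),
            "ref_freq": ref.freq_per_1000[c],
            "ratio": round(ratios[c], 4) if not math.isnan(ratios[c]) else math.nan,
            "indicative": c in indic,
        }
        for c in ALL_CODONS
    ]
    return pd.DataFrame(rows)
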