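"""Identification of translationally optimal codons.

Genes at the two extremes of correspondence-analysis axis 1 are pooled; the
tail with the lower mean ENc is treated as the putatively highly expressed
("high") pool. For every sense codon the pooled usage of the two tails is
compared with a per-codon 2x2 Pearson chi-squared contingency test

    [[n_high(codon), n_high(family) - n_high(codon)],
     [n_low(codon),  n_low(family)  - n_low(codon)]]

without continuity correction and without multiple-testing adjustment.
A codon is called optimal when p < alpha (0.01 by default) AND its relative
synonymous frequency is higher in the high pool. Met, Trp and stop codons
are never called optimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import CodonCountTable, GeneMetrics, count_codons, rscu
from .genetic_code import CODON_TO_AA, DEGENERATE_AAS, SYN_FAMILIES
from .multivariate import Ordination

__all__ = ["OptimalCodonTable", "select_extreme_pools", "chi2_optimal"]


@dataclass
class OptimalCodonTable:
    """Per-codon contingency results in the shape of a published optimal-codon table.

    ``table`` columns: amino_acid, codon, rscu_high, n_high, rscu_low, n_low,
    chi2, p, optimal, testable.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def optimal_codons(self) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["optimal"], "codon"])

    def write_tsv(self, path: str | Path) -> None:
        df = self.table.copy()
        df["codon"] = df["codon"].str.replace("T", "U")
        df["rscu_high"] = df["rscu_high"].round(2)
        df["rscu_low"] = df["rscu_low"].round(2)
        df["chi2"] = df["chi2"].round(4)
        df["star"] = np.where(df["optimal"], "*", "")
        df.to_csv(path, sep="\t", index=False)


def select_extreme_pools(
    ordination: Ordination,
    genes: Sequence[GeneMetrics],
    fraction: float = 0.05,
) -> tuple[list[GeneMetrics], list[GeneMetrics]]:
    """Take the two axis-1 tails and label them by expression proxy.

    Genes are ranked by their axis-1 coordinate (ties broken by gene id so
    the pools are deterministic); each tail holds ``ceil(fraction * n)``
    genes. The tail with the lower mean ENc is returned first as the
    putatively highly expressed pool, the other second.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    by_id = {g.id: g for g in genes}
    coords = ordination.row_coords["axis1"]
    ids = [i for i in coords.index if i in by_id]
    n = len(ids)
    n_tail = math.ceil(fraction * n)
    if n_tail < 1 or 2 * n_tail > n:
        raise ValueError(f"cannot take two tails of {n_tail} from {n} genes")
    ranked = sorted(ids, key=lambda i: (coords[i], i))
    bottom = [by_id[i] for i in ranked[:n_tail]]
    top = [by_id[i] for i in ranked[-n_tail:]]
    mean_enc = lambda pool: np.nanmean([g.enc for g in pool])
    if mean_enc(top) <= mean_enc(bottom):
        return top, bottom
    return bottom, top


def chi2_optimal(
    high: CodonCountTable | Sequence[GeneMetrics],
    low: CodonCountTable | Sequence[GeneMetrics],
    alpha: float = 0.01,
    yates: bool = False,
) -> OptimalCodonTable:
    """Per-codon chi-squared comparison of the high and low pools.

    Accepts pooled count tables directly, or gene lists to pool. Codons in
    families absent from either pool are flagged untestable (never optimal).
    """
    high_t = _pool(high)
    low_t = _pool(low)
    if high_t.n_codons == 0 or low_t.n_codons == 0:
        raise ValueError("both pools must be non-empty")
    rscu_h = rscu(high_t, include_stops=True)
    rscu_l = rscu(low_t, include_stops=True)
    rows = []
    for aa in sorted(SYN_FAMILIES):
        fam = SYN_FAMILIES[aa]
        fam_h = sum(high_t.counts[c] for c in fam)
        fam_l = sum(low_t.counts[c] for c in fam)
        for codon in fam:
            nh, nl = high_t.counts[codon], low_t.counts[codon]
            chi2 = p = math.nan
            optimal = False
            testable = (
                len(fam) > 1 and fam_h > 0 and fam_l > 0
            )
            if testable:
                obs = np.array([[nh, fam_h - nh], [nl, fam_l - nl]])
                if obs[:, 0].sum() == 0 or obs[:, 1].sum() == 0:
                    chi2, p = 0.0, 1.0  # codon (or its synonyms) unused in both pools
                else:
                    res = stats.chi2_contingency(obs, correction=yates)
                    chi2, p = float(res.statistic), float(res.pvalue)
                optimal = bool(p < alpha and nh / fam_h > nl / fam_l)
            rows.append(
                {
                    "amino_acid": aa,
                    "codon": codon,
                    "rscu_high": rscu_h[codon],
                    "n_high": nh,
                    "rscu_low": rscu_l[codon],
                    "n_low": nl,
                    "chi2": chi2,
                    "p": p,
                    "optimal": optimal,
                    "testable": testable,
                }
            )
    table = pd.DataFrame(rows)
    _check_family_bound(table)
    return OptimalCodonTable(table=table, alpha=alpha)


def _pool(x: CodonCountTable | Sequence[GeneMetrics]) -> CodonCountTable:
    if isinstance(x, CodonCountTable):
        return x
    pooled = CodonCountTable()
    for g in x:
        pooled = pooled + g.counts
    return pooled


def _check_family_bound(table: pd.DataFrame) -> None:
    # a k-fold family cannot have k optimal codons: some synonym's relative
    # frequency must drop when another's rises
    for aa, grp in table.groupby("amino_acid"):
        k = len(SYN_FAMILIES[aa])
        n_opt = int(grp["optimal"].sum())
        if k > 1 and n_opt >= k:
            raise AssertionError(
                f"{aa}: {n_opt} of {k} codons flagged optimal — impossible"
            )
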