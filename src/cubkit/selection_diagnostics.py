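"""Mutation-versus-selection diagnostics.

Three classical graphical/statistical diagnostics for whether synonymous
codon usage is explained by compositional (mutational) bias alone:

* the ENc plot — observed ENc against GC3s, against the mutation-only
  expectation curve ENc(S); genes falling well below the curve are under
  constraints beyond G+C mutation bias;
* the relative ENc deviation (ENc_expected - ENc_observed) / ENc_expected
  and its frequency distribution;
* the neutrality plot — OLS regression of GC12 on GC3; a slope of 1 means
  complete neutrality (mutation pressure acts equally at all positions),
  a slope of 0 complete selective constraint, and slope × 100 is read as
  the percentage contribution of directional mutation pressure.

Plus Spearman rank-correlation matrices between arbitrary per-gene indices
(mid-rank ties, two-tailed p, pairwise-complete observations).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import GeneMetrics, expected_enc, metrics_table

logger = logging.getLogger(__name__)

__all__ = [
    "NeutralityFit",
    "CorrelationMatrix",
    "enc_plot",
    "enc_deviation",
    "histogram",
    "gc_histogram",
    "neutrality_fit",
    "spearman_matrix",
]


def _as_table(genes: Sequence[GeneMetrics] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(genes, pd.DataFrame):
        return genes
    return metrics_table(genes)


@dataclass(frozen=True)
class NeutralityFit:
    """OLS fit of GC12 on GC3 and its mutation/selection reading."""

    slope: float
    intercept: float
    r2: float
    pearson_r: float
    p_value: float
    n: int

    @property
    def mutation_pct(self) -> float:
        """Directional mutation pressure contribution, slope x 100."""
        return self.slope * 100.0

    @property
    def other_pct(self) -> float:
        """Everything else (e.g. selection), (1 - slope) x 100."""
        return (1.0 - self.slope) * 100.0


@dataclass(frozen=True)
class CorrelationMatrix:
    """Spearman rho and two-tailed p for every variable pair."""

    variables: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame


def enc_plot(
    genes: Sequence[GeneMetrics] | pd.DataFrame, curve_points: int = 101
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Data for an ENc plot: per-gene (gc3s, enc) points and the expected curve.

    Genes lacking a defined ENc or GC3s are omitted (logged). The curve is
    sampled uniformly on S in [0, 1].
    """
    df = _as_table(genes)
    pts = df[["gc3s", "enc"]].dropna()
    n_dropped = len(df) - len(pts)
    if n_dropped:
        logger.info("enc_plot: %d genes without defined ENc/GC3s omitted", n_dropped)
    s = np.linspace(0.0, 1.0, curve_points)
    curve = pd.DataFrame({"s": s, "expected_enc": [expected_enc(v) for v in s]})
    return pts.reset_index(), curve


def enc_deviation(genes: Sequence[GeneMetrics] | pd.DataFrame) -> pd.Series:
    """Relative ENc deviation (ENc_exp - ENc_obs) / ENc_exp per gene.

    Positive values mean the gene is more biased than its GC3s alone
    predicts. Genes without defined ENc/GC3s are omitted.
    """
    df = _as_table(genes)[["gc3s", "enc"]].dropna()
    exp = df["gc3s"].map(expected_enc)
    return ((exp - df["enc"]) / exp).rename("enc_deviation")


def histogram(values: Sequence[float] | pd.Series, bin_width: float = 0.05,
              lo: float | None = None, hi: float | None = None) -> pd.DataFrame:
    """Counts per closed-left bin [edge, edge + width) covering the data."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    lo = math.floor((v.min() if lo is None else lo) / bin_width) * bin_width
    hi_v = v.max() if hi is None else hi
    n_bins = max(1, math.ceil((hi_v - lo) / bin_width + 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)
    idx = np.minimum(((v - lo) / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def gc_histogram(
    genes: Sequence[GeneMetrics] | pd.DataFrame, bin_width: float = 0.05
) -> pd.DataFrame:
    """GC-content distribution over closed-left bins within [0, 1]."""
    df = _as_table(genes)
    return histogram(df["gc"], bin_width=bin_width)


def neutrality_fit(genes: Sequence[GeneMetrics] | pd.DataFrame) -> NeutralityFit:
    """Ordinary least squares of GC12 on GC3 with a two-tailed slope test."""
    df = _as_table(genes)[["gc3", "gc12"]].dropna()
    if len(df) < 3:
        raise ValueError("neutrality fit needs at least 3 genes")
    if np.ptp(df["gc3"].to_numpy()) == 0:
        raise ValueError("GC3 has zero variance: slope undefined")
    res = stats.linregress(df["gc3"], df["gc12"])
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(df),
    )


def spearman_matrix(
    table: pd.DataFrame, variables: Sequence[str] | None = None
) -> CorrelationMatrix:
    """Spearman rank correlations (mid-rank ties) with pairwise-complete data.

    Constant variables yield NaN rho/p for their pairs (flagged via log).
    The diagonal is exactly 1 with p = 0.
    """
    if variables is None:
        variables = [c for c in table.columns if table[c].dtype.kind in "fi"]
    variables = tuple(variables)
    k = len(variables)
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            pair = table[[variables[i], variables[j]]].dropna()
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() < 2 or y.nunique() < 2:
                logger.warning(
                    "constant variable in pair (%s, %s): rho undefined",
                    variables[i],
                    variables[j],
                )
                continue
            r = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = float(r.statistic)
            p[i, j] = p[j, i] = float(r.pvalue)
    return CorrelationMatrix(
        variables=variables,
        rho=pd.DataFrame(rho, index=variables, columns=variables),
        p=pd.DataFrame(p, index=variables, columns=variables),
    )


def significance_stars(p: float) -> str:
    """Report notation: '**' for p < 0.01, '*' for p < 0.05, '' otherwise."""
    if math.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def write_correlation_tsv(cm: CorrelationMatrix, path: str | Path) -> None:
    """Lower-triangular correlation report with significance stars."""
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(cm.variables) + "\n")
        for i, vi in enumerate(cm.variables):
            cells = []
            for j in range(len(cm.variables)):
                if j >= i:
                    cells.append("")
                    continue
                r = cm.rho.iloc[i, j]
                pv = cm.p.iloc[i, j]
                cells.append(
                    "" if math.isnan(r) else f"{r:.3f}{significance_stars(pv)}"
                )
            fh.write(vi + "\t" + "\t".join(cells) + "\n")
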