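"""Correspondence analysis (COA) of codon and amino-acid usage.

Classical CA treats a non-negative genes × codons table in the chi-squared
metric: with correspondence matrix P = X / grand total, row masses r and
column masses c, the standardized residuals

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2}

are decomposed by SVD; principal coordinates are the mass-rescaled singular
vectors scaled by the singular values, and each axis explains a fraction
sigma_i^2 / sum(sigma^2) of the total inertia (which equals the table's
chi-squared statistic divided by its grand total).

Following codonW practice, CA of synonymous usage is run on the 59-column
RSCU matrix (61 sense codons minus Met and Trp), which removes amino-acid
composition effects; a separate 20-column amino-acid frequency matrix
captures those effects instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .codon_metrics import GeneMetrics
from .genetic_code import AA_ORDER, CODONS_59

logger = logging.getLogger(__name__)

__all__ = [
    "Ordination",
    "build_rscu_matrix",
    "build_aa_matrix",
    "correspondence_analysis",
    "classify_genes_by_gc",
]


@dataclass
class Ordination:
    """Result of a correspondence analysis."""

    row_coords: pd.DataFrame  # genes x axes, principal coordinates
    col_coords: pd.DataFrame  # columns x axes, principal coordinates
    inertia_fraction: np.ndarray  # per retained axis, in [0, 1]
    total_inertia: float
    singular_values: np.ndarray  # all non-trivial singular values

    @property
    def n_axes(self) -> int:
        return self.row_coords.shape[1]


def build_rscu_matrix(genes: Sequence[GeneMetrics]) -> pd.DataFrame:
    """Genes × 59 sense codons matrix of RSCU values.

    Column order is fixed (amino acid, then codon alphabetically).
    Families absent from a gene (NaN RSCU) contribute 0 so the row set
    stays identical across pipeline stages.
    """
    if not genes:
        raise ValueError("empty gene list")
    data = np.zeros((len(genes), len(CODONS_59)))
    for i, g in enumerate(genes):
        for j, codon in enumerate(CODONS_59):
            v = g.rscu.get(codon, np.nan)
            data[i, j] = 0.0 if np.isnan(v) else v
    return pd.DataFrame(data, index=[g.id for g in genes], columns=list(CODONS_59))


def build_aa_matrix(genes: Sequence[GeneMetrics]) -> pd.DataFrame:
    """Genes × 20 amino-acid relative-frequency matrix (rows sum to 1)."""
    if not genes:
        raise ValueError("empty gene list")
    data = np.zeros((len(genes), len(AA_ORDER)))
    for i, g in enumerate(genes):
        aa_counts = g.counts.aa_counts()
        total = sum(aa_counts.values())
        if total == 0:
            raise ValueError(f"{g.id}: no residues")
        data[i] = [aa_counts[aa] / total for aa in AA_ORDER]
    return pd.DataFrame(data, index=[g.id for g in genes], columns=list(AA_ORDER))


def correspondence_analysis(matrix: pd.DataFrame, n_axes: int = 20) -> Ordination:
    """Classical correspondence analysis of a non-negative table.

    Zero rows/columns are dropped with a warning (their chi-squared profile
    is undefined). Axis signs are arbitrary in CA; for reproducibility each
    axis is oriented so the column with the largest |coordinate| is positive.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("correspondence analysis requires a non-negative table")
    row_ok = x.sum(axis=1) > 0
    col_ok = x.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        logger.warning(
            "dropping %d zero rows and %d zero columns before CA",
            (~row_ok).sum(),
            (~col_ok).sum(),
        )
        matrix = matrix.loc[row_ok, col_ok]
        x = matrix.to_numpy(dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("table grand total must be positive")
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    # discard numerically-zero axes (the trivial dimension is already removed
    # by centering; rank-deficient tables simply have fewer axes)
    keep = sv > max(sv[0], 1.0) * 1e-12 if sv.size else np.zeros(0, bool)
    u, sv, vt = u[:, keep], sv[keep], vt[keep]
    total_inertia = float((sv**2).sum())
    if sv.size == 0:
        # degenerate table (all rows proportional): a single all-zero axis
        axes = ["axis1"]
        return Ordination(
            row_coords=pd.DataFrame(0.0, index=matrix.index, columns=axes),
            col_coords=pd.DataFrame(0.0, index=matrix.columns, columns=axes),
            inertia_fraction=np.zeros(1),
            total_inertia=0.0,
            singular_values=sv,
        )
    k = min(n_axes, sv.size)
    row_std = u[:, :k] / np.sqrt(r)[:, None]
    col_std = vt[:k].T / np.sqrt(c)[:, None]
    row_pc = row_std * sv[:k]
    col_pc = col_std * sv[:k]
    # orientation: the column with the largest |loading| on each axis is positive
    for a in range(k):
        j = int(np.argmax(np.abs(col_pc[:, a])))
        if col_pc[j, a] < 0:
            col_pc[:, a] *= -1
            row_pc[:, a] *= -1
    axes = [f"axis{i + 1}" for i in range(k)]
    frac = sv**2 / total_inertia if total_inertia > 0 else np.zeros_like(sv)
    return Ordination(
        row_coords=pd.DataFrame(row_pc, index=matrix.index, columns=axes),
        col_coords=pd.DataFrame(col_pc, index=matrix.columns, columns=axes),
        inertia_fraction=frac[:k],
        total_inertia=total_inertia,
        singular_values=sv,
    )


def classify_genes_by_gc(
    gc: Sequence[float] | pd.Series, breaks: tuple[float, float] = (0.45, 0.60)
) -> list[str]:
    """Three GC-content classes with half-open intervals.

    "low" for GC < breaks[0], "mid" for breaks[0] <= GC < breaks[1],
    "high" for GC >= breaks[1].
    """
    lo, hi = breaks
    out = []
    for v in np.asarray(gc, dtype=float):
        if v < lo:
            out.append("low")
        elif v < hi:
            out.append("mid")
        else:
            out.append("high")
    return out
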