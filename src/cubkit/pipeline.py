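"""End-to-end orchestration of the codon-usage analysis.

Runs QC -> per-gene indices -> correspondence analysis -> mutation/selection
diagnostics -> optimal-codon detection -> cross-species comparison, writing
every report table as TSV plus a machine-readable JSON run summary. A stage
failure aborts the run, names the stage, and removes partial outputs so an
output directory is either complete or empty.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import cds_io, codon_metrics, multivariate, optimal_codons, selection_diagnostics
from .species_comparison import comparison_table, read_kazusa

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunSummary", "run"]

#: per-gene index variables entering the correlation matrix
_CORR_VARS = (
    "length_nt", "gc", "gc1", "gc2", "gc3", "gc3s",
    "a3s", "t3s", "c3s", "g3s", "gravy", "aromo", "enc", "cai",
    "axis1", "axis2",
)


@dataclass
class RunConfig:
    input_fasta: str | Path
    output_dir: str | Path
    reference_fasta: str | Path | None = None  # CAI reference (e.g. ribosomal)
    blacklist_ids: str | Path | None = None
    comparison_tables: Sequence[str | Path] = field(default_factory=tuple)
    extreme_fraction: float = 0.05
    alpha: float = 0.01
    min_length_nt: int = 300
    n_axes: int = 20
    seed: int = 0


@dataclass
class RunSummary:
    n_input: int
    n_passed: int
    n_failed: int
    files: list[str]
    config: dict
    headline: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_passed": self.n_passed,
                "n_failed": self.n_failed,
                "files": self.files,
                "config": self.config,
                "headline": self.headline,
            },
            indent=2,
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run(config: RunConfig) -> RunSummary:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str) -> Path:
        p = out_dir / name
        written.append(p)
        return p

    stage = "cds_io"
    try:
        seqs = cds_io.read_fasta(config.input_fasta)
        blacklist = (
            cds_io.read_id_list(config.blacklist_ids)
            if config.blacklist_ids
            else None
        )
        passed, reports = cds_io.qc_filter(
            seqs, min_length_nt=config.min_length_nt, blacklist_ids=blacklist
        )
        cds_io.write_qc_report(reports, emit("qc_report.tsv"))
        logger.info("QC: %d of %d sequences passed", len(passed), len(seqs))
        if len(passed) < 3:
            raise ValueError(f"only {len(passed)} sequences passed QC; need >= 3")

        stage = "codon_metrics"
        weights = None
        if config.reference_fasta:
            ref_seqs = cds_io.read_fasta(config.reference_fasta)
            ref_passed, _ = cds_io.qc_filter(
                ref_seqs, min_length_nt=config.min_length_nt
            )
            if ref_passed:
                weights = codon_metrics.cai_weights(
                    (codon_metrics.count_codons(s) for s in ref_passed),
                    source_ids=[s.id for s in ref_passed],
                )
            else:
                logger.warning("no reference sequence passed QC; CAI left empty")
        else:
            logger.warning("no CAI reference supplied; CAI column left empty")
        genes = [codon_metrics.compute_gene_metrics(s, weights) for s in passed]
        codon_metrics.write_metrics_tsv(genes, emit("gene_metrics.tsv"))
        pooled = codon_metrics.count_codons(passed)
        codon_metrics.write_codon_usage_tsv(pooled, emit("codon_usage.tsv"))

        stage = "multivariate"
        rscu_m = multivariate.build_rscu_matrix(genes)
        ordination = multivariate.correspondence_analysis(rscu_m, n_axes=config.n_axes)
        metrics = codon_metrics.metrics_table(genes)
        gene_coords = ordination.row_coords.copy()
        gene_coords["gc_class"] = multivariate.classify_genes_by_gc(
            metrics.loc[gene_coords.index, "gc"]
        )
        gene_coords.round(6).to_csv(emit("coa_genes.tsv"), sep="\t", index_label="id")
        codon_coords = ordination.col_coords.copy()
        codon_coords["third_base"] = [c[2].replace("T", "U") for c in codon_coords.index]
        codon_coords.index = codon_coords.index.str.replace("T", "U")
        codon_coords.round(6).to_csv(
            emit("coa_codons.tsv"), sep="\t", index_label="codon"
        )
        inertia = pd.DataFrame(
            {
                "axis": range(1, ordination.singular_values.size + 1),
                "inertia": ordination.singular_values**2,
                "fraction": ordination.singular_values**2 / ordination.total_inertia,
            }
        )
        inertia["cumulative_fraction"] = inertia["fraction"].cumsum()
        inertia.round(6).to_csv(emit("coa_inertia.tsv"), sep="\t", index=False)

        stage = "selection_diagnostics"
        points, curve = selection_diagnostics.enc_plot(metrics)
        points.round(6).to_csv(emit("enc_plot.tsv"), sep="\t", index=False)
        curve.round(6).to_csv(emit("enc_plot_curve.tsv"), sep="\t", index=False)
        dev = selection_diagnostics.enc_deviation(metrics)
        selection_diagnostics.histogram(dev).to_csv(
            emit("enc_deviation.tsv"), sep="\t", index=False
        )
        try:
            fit = selection_diagnostics.neutrality_fit(metrics)
            pd.DataFrame(
                [
                    {
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "r2": fit.r2,
                        "pearson_r": fit.pearson_r,
                        "p_value": fit.p_value,
                        "n": fit.n,
                        "mutation_pct": fit.mutation_pct,
                        "other_pct": fit.other_pct,
                    }
                ]
            ).round(6).to_csv(emit("neutrality.tsv"), sep="\t", index=False)
            neutrality_slope = fit.slope
        except ValueError as e:
            logger.warning("neutrality fit skipped: %s", e)
            neutrality_slope = math.nan
        corr_input = metrics.join(ordination.row_coords[["axis1", "axis2"]])
        corr_vars = [v for v in _CORR_VARS if v in corr_input.columns]
        cm = selection_diagnostics.spearman_matrix(corr_input, corr_vars)
        selection_diagnostics.write_correlation_tsv(cm, emit("correlations.tsv"))
        selection_diagnostics.gc_histogram(metrics).to_csv(
            emit("gc_histogram.tsv"), sep="\t", index=False
        )

        stage = "optimal_codons"
        high, low = optimal_codons.select_extreme_pools(
            ordination, genes, fraction=config.extreme_fraction
        )
        oct_result = optimal_codons.chi2_optimal(high, low, alpha=config.alpha)
        oct_result.write_tsv(emit("optimal_codons.tsv"))

        stage = "species_comparison"
        comparisons = {}
        for table_path in config.comparison_tables:
            ref = read_kazusa(table_path)
            ct = comparison_table(pooled, ref)
            ct.to_csv(emit(f"comparison_{ref.organism}.tsv"), sep="\t", index=False)
            comparisons[ref.organism] = int(ct["indicative"].sum())

        stage = "summary"
        summary = RunSummary(
            n_input=len(seqs),
            n_passed=len(passed),
            n_failed=len(seqs) - len(passed),
            files=sorted(p.name for p in written) + ["run_summary.json"],
            config={
                "input_fasta": str(config.input_fasta),
                "reference_fasta": (
                    str(config.reference_fasta) if config.reference_fasta else None
                ),
                "blacklist_ids": (
                    str(config.blacklist_ids) if config.blacklist_ids else None
                ),
                "extreme_fraction": config.extreme_fraction,
                "alpha": config.alpha,
                "min_length_nt": config.min_length_nt,
                "n_axes": config.n_axes,
                "seed": config.seed,
            },
            headline={
                "axis1_inertia_pct": round(100 * float(ordination.inertia_fraction[0]), 4),
                "axis2_inertia_pct": (
                    round(100 * float(ordination.inertia_fraction[1]), 4)
                    if ordination.inertia_fraction.size > 1
                    else None
                ),
                "neutrality_slope": (
                    None if math.isnan(neutrality_slope) else round(neutrality_slope, 6)
                ),
                "n_optimal_codons": len(oct_result.optimal_codons),
                "optimal_codons": sorted(
                    c.replace("T", "U") for c in oct_result.optimal_codons
                ),
                "indicative_codons_per_organism": comparisons,
                "mean_enc": round(float(metrics["enc"].mean()), 4),
                "n_high_bias_genes_enc_lt_35": int((metrics["enc"] < 35).sum()),
            },
        )
        (out_dir / "run_summary.json").write_text(summary.to_json() + "\n")
        return summary
    except Exception as e:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(e, StageError):
            raise
        raise StageError(stage, e) from e
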