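"""End-to-end pipeline: QC -> normalize -> traits -> impute -> statistics.

The stage order mirrors the analysis workflow: peaks are quality-filtered,
areas normalized to per-class fractional abundances, replicates averaged,
missing glycans imputed with a constant pseudo-abundance, derived traits
computed, and the multivariate layer (PCA with Hotelling T^2, trait-gene
Pearson correlations, rCCA of traits vs transcription factors with
hierarchical ordering of the similarity map) run on the completed data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .glycan_model import GlycanRecord
from .library import default_library, read_annotation_table
from .quant_qc import (
    IDOTP_MIN_DEFAULT, IMPUTE_VALUE_DEFAULT, SNR_MIN_DEFAULT,
    impute_missing, pivot_areas, qc_filter, replicate_rsd, to_fractional, zscore_features,
)
from .stats_integration import (
    PCAModel, RCCAModel, cluster_order, correlate_traits_genes, fit_pca, fit_rcca, hotelling_t2,
)
from .trait_engine import TraitMatrix, builtin_traits, derive_traits, fab_group_summary

log = logging.getLogger("glycotraits")

#: default hematopoietic transcription-factor panel for the rCCA block
DEFAULT_TF_GENES = ["TAL1", "GATA1", "GATA2", "GATA3", "SPI1", "CEBPA", "CBFA2T3"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run; defaults are the
    workflow's standard settings (QC thresholds 0.85 / 6 / RT required,
    0.01 imputation constant, unit-variance PCA with two components,
    rCCA lambda 0.1 / 0.1 with two components)."""

    quant_path: str | None = None
    annotation_path: str | None = None
    expression_path: str | None = None
    metadata_path: str | None = None
    output_dir: str = "glycotraits_out"
    idotp_min: float = IDOTP_MIN_DEFAULT
    snr_min: float = SNR_MIN_DEFAULT
    require_rt: bool = True
    impute_value: float = IMPUTE_VALUE_DEFAULT
    pca_scaling: str = "unit_variance"
    pca_components: int = 2
    rcca_lambda1: float = 0.1
    rcca_lambda2: float = 0.1
    rcca_components: int = 2
    tf_genes: list[str] = field(default_factory=lambda: list(DEFAULT_TF_GENES))
    correlation_pairs: list[tuple[str, str]] | None = None
    seed: int = 0


@dataclass
class PipelineResult:
    abundances: pd.DataFrame          # samples x glycans, percent, imputed
    imputed_mask: pd.DataFrame
    traits: TraitMatrix
    fab_summary: pd.DataFrame | None
    pca: PCAModel
    t2_flags: pd.DataFrame
    correlations: pd.DataFrame | None
    rcca: RCCAModel | None
    rcca_row_order: list | None
    rcca_col_order: list | None
    rejection_log: pd.DataFrame
    replicate_rsd_table: pd.DataFrame | None
    replicate_rsd_average: float | None


def run_pipeline(
    config: PipelineConfig,
    quant: pd.DataFrame | None = None,
    library: list[GlycanRecord] | None = None,
    expression: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute all stages on in-memory tables or the paths in ``config``.

    Tables passed directly take precedence over paths; the packaged glycan
    library is the fallback annotation source.
    """
    if quant is None:
        if config.quant_path is None:
            raise ValueError("no quantification table given")
        quant = gio.read_quant_table(config.quant_path)
    if library is None:
        library = (read_annotation_table(config.annotation_path)
                   if config.annotation_path else default_library())
    if expression is None and config.expression_path:
        expression = gio.read_expression(config.expression_path)
    if metadata is None and config.metadata_path:
        metadata = gio.read_metadata(config.metadata_path)

    log.info("QC filter: idotp >= %s, S/N >= %s, rt required=%s",
             config.idotp_min, config.snr_min, config.require_rt)
    kept, rejected = qc_filter(quant, config.idotp_min, config.snr_min, config.require_rt)
    log.info("QC kept %d / %d peak records", len(kept), len(quant))
    if kept.empty:
        raise ValueError("no peak passed the quality criteria; check thresholds")

    # replicate precision on the one sample with >1 replicate, if any
    rsd_table = rsd_avg = None
    rep_counts = kept.groupby("sample")["replicate"].nunique()
    rep_samples = rep_counts[rep_counts >= 2].index
    if len(rep_samples):
        rep_long = kept[kept["sample"].isin(rep_samples[:1])]
        rep_areas = pivot_areas(rep_long, average_replicates=False)
        rep_frac = to_fractional(rep_areas)
        rsd_table, rsd_avg = replicate_rsd(rep_frac.droplevel("sample"))
        log.info("replicate RSD (sample %s): %.2f%%", rep_samples[0], rsd_avg)

    areas = pivot_areas(kept, average_replicates=True)
    frac = to_fractional(areas)
    abundances, mask = impute_missing(frac, config.impute_value)

    traits = derive_traits(abundances, library, builtin_traits())
    fab_summary = None
    if metadata is not None:
        fab_summary = fab_group_summary(traits, metadata["fab"])

    # PCA on glycans + traits jointly (ratio traits excluded: unbounded scale)
    ratio_cols = [t.trait_name for t in traits.traits if t.output == "ratio"]
    trait_vals = traits.values.drop(columns=ratio_cols)
    combined = pd.concat([abundances, trait_vals], axis=1).dropna(axis=1)
    pca = fit_pca(combined, n_components=config.pca_components, scaling=config.pca_scaling)
    t2 = hotelling_t2(pca)

    correlations = rcca = None
    row_order = col_order = None
    if expression is not None:
        gst = [g for g in expression.columns if g not in config.tf_genes]
        correlations = correlate_traits_genes(
            traits.values, expression[gst], pairs=config.correlation_pairs)
        tf_present = [g for g in config.tf_genes if g in expression.columns]
        if len(tf_present) >= 2:
            X = zscore_features(trait_vals.dropna(axis=1))
            Y = zscore_features(expression.loc[X.index, tf_present])
            K = min(config.rcca_components, X.shape[1], Y.shape[1])
            rcca = fit_rcca(X, Y, config.rcca_lambda1, config.rcca_lambda2, K)
            row_order, col_order, _, _ = cluster_order(rcca.similarity)

    return PipelineResult(
        abundances=abundances, imputed_mask=mask, traits=traits,
        fab_summary=fab_summary, pca=pca, t2_flags=t2,
        correlations=correlations, rcca=rcca,
        rcca_row_order=row_order, rcca_col_order=col_order,
        rejection_log=rejected, replicate_rsd_table=rsd_table,
        replicate_rsd_average=rsd_avg,
    )


def write_result(result: PipelineResult, outdir: str | Path, config: PipelineConfig | None = None) -> None:
    """Persist all result tables (TSV/CSV/JSON) plus a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_matrix(result.abundances, outdir / "abundances.tsv", units="percent")
    gio.write_trait_matrix(result.traits, outdir / "traits.tsv")
    if result.fab_summary is not None:
        result.fab_summary.to_csv(outdir / "fab_summary.tsv", sep="\t")
    result.pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    result.pca.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t")
    result.t2_flags.to_csv(outdir / "hotelling_t2.tsv", sep="\t")
    if result.correlations is not None:
        result.correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    if result.rcca is not None:
        result.rcca.similarity.to_csv(outdir / "rcca_similarity.tsv", sep="\t")
        np.savetxt(outdir / "rcca_canonical_correlations.tsv",
                   result.rcca.canonical_correlations, fmt="%.6f")
    result.rejection_log.to_csv(outdir / "qc_rejections.csv", index=False)
    if result.replicate_rsd_table is not None:
        result.replicate_rsd_table.to_csv(outdir / "replicate_rsd.tsv", sep="\t")
    if config is not None:
        import json
        (outdir / "run_config.json").write_text(json.dumps(asdict(config), indent=1, default=str))
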