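"""End-to-end pipeline drivers: harmonize -> QC -> differential expression
-> candidate screen, and the cohort verification report.

Every threshold and seed actually used is logged so that runs are
auditable, and outputs are deterministic for a fixed configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, harmonize, io, screen
from .containers import (
    CLASS_BC,
    CLASS_BLADDER,
    CLASS_UTI,
    COHORT_GROUPS,
    ExpressionMatrix,
)
from .diffexpr import ContrastSpec, run_contrast
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger("urimark")

__all__ = ["RunConfig", "ScreenResult", "screen_pipeline", "run_screen",
           "clinical_report", "run_clinical"]

#: kidney compartments and their disease/normal class labels
COMPARTMENTS = {
    "glomeruli": ("dkd_glomeruli", "normal_glomeruli"),
    "tubules": ("dkd_tubules", "normal_tubules"),
}


@dataclass
class RunConfig:
    """Thresholds and paths for the pipeline entry points."""

    expression_path: str | None = None
    samples_path: str | None = None
    cohort_path: str | None = None
    dilution_path: str | None = None
    outdir: str = "."
    alpha: float = 0.05
    fc_min: float = 2.0
    rle_bias_threshold: float = 0.15
    batch_r2_threshold: float = 0.5
    n_pcs: int = 2
    low_expr_percentile: float = 25.0
    top_k: int = 8
    detect_threshold: float = 5.0
    fold_decimals: int = 1
    cv_decimals: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError("alpha must be in [0, 1]")
        if self.fc_min < 1.0:
            raise ConfigurationError("fc_min must be >= 1")
        if self.rle_bias_threshold < 0:
            raise ConfigurationError("rle_bias_threshold must be >= 0")
        if not 0.0 < self.batch_r2_threshold <= 1.0:
            raise ConfigurationError("batch_r2_threshold must be in (0, 1]")
        if not 0.0 < self.low_expr_percentile <= 100.0:
            raise ConfigurationError("low_expr_percentile must be in (0, 100]")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")


@dataclass
class ScreenResult:
    candidates: pd.DataFrame
    contrasts: dict[str, pd.DataFrame]
    qc: dict
    venn: dict[str, screen.VennResult] = field(default_factory=dict)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, KeyboardInterrupt):
                raise type(exc)(f"[stage {name}] {exc}") from exc
            return False

    return _Ctx()


def screen_pipeline(m: ExpressionMatrix, cfg: RunConfig) -> ScreenResult:
    """Run the candidate screen on an in-memory compendium.

    Stages: per-platform split and shared-feature intersection; array QC
    on the raw pool (scale factors, RLE consistency screen, PCA batch
    scoring — all before normalization, since quantile normalization
    erases exactly the additive per-dataset biases these diagnostics look
    for); discard of RLE-flagged datasets; quantile normalization; one
    moderated-t contrast per screening comparison; then the type-1 and
    type-2 selection rules per kidney compartment present in the data.
    """
    logger.info(
        "screen: alpha=%g fc_min=%g rle_bias=%g batch_r2=%g "
        "low_expr_pct=%g top_k=%d seed=%d",
        cfg.alpha, cfg.fc_min, cfg.rle_bias_threshold,
        cfg.batch_r2_threshold, cfg.low_expr_percentile, cfg.top_k, cfg.seed,
    )
    with _stage("harmonize"):
        per_platform = harmonize.split_by_platform(m)
        pooled = harmonize.intersect_platform_features(per_platform)
        if pooled.has_missing():
            keep = pooled.values.index[~pooled.values.isna().any(axis=1)]
            pooled = pooled.subset_genes(list(keep))
        logger.info(
            "harmonize: %d platforms -> %d shared features, %d samples",
            len(per_platform), pooled.n_genes, pooled.n_samples,
        )

    with _stage("qc"):
        rle = harmonize.rle_screen(pooled, cfg.rle_bias_threshold)
        dropped = rle.flagged_datasets()
        # never discard every dataset of a tissue class: a biased-but-only
        # dataset is kept (and logged) rather than silently deleting the class
        ds_class = pooled.samples.drop_duplicates("dataset_id").set_index(
            "dataset_id"
        )["tissue_class"]
        for cls in ds_class.unique():
            cls_datasets = set(ds_class.index[ds_class == cls])
            if cls_datasets <= set(dropped):
                keep_one = sorted(cls_datasets)[0]
                logger.warning(
                    "qc: all datasets of class %s flagged; keeping %s",
                    cls, keep_one,
                )
                dropped = [d for d in dropped if d != keep_one]
        if dropped:
            logger.info("qc: discarding biased datasets %s", dropped)
            keep = list(
                pooled.samples.index[~pooled.samples["dataset_id"].isin(dropped)]
            )
            pooled = pooled.subset_samples(keep)
            rle = harmonize.rle_screen(pooled, cfg.rle_bias_threshold)
        metrics = harmonize.array_qc_metrics(pooled, cfg.detect_threshold)
        pca = harmonize.pca_batch_score(
            pooled, cfg.n_pcs, cfg.batch_r2_threshold
        )
        normalized = harmonize.quantile_normalize(pooled)
        qc = {
            "n_features": normalized.n_genes,
            "n_samples": normalized.n_samples,
            "discarded_datasets": dropped,
            "rle_median_range": [
                float(rle.per_sample["rle_median"].min()),
                float(rle.per_sample["rle_median"].max()),
            ],
            "scale_factor_range": [
                float(metrics["scale_factor"].min()),
                float(metrics["scale_factor"].max()),
            ],
            "batch_r2": [float(v) for v in pca.batch_r2],
            "biology_r2": [float(v) for v in pca.biology_r2],
            "batch_r2_within": [float(v) for v in pca.batch_r2_within],
            "batch_flag": pca.batch_flag,
            "thresholds": {
                "alpha": cfg.alpha,
                "fc_min": cfg.fc_min,
                "rle_bias_threshold": cfg.rle_bias_threshold,
                "batch_r2_threshold": cfg.batch_r2_threshold,
                "low_expr_percentile": cfg.low_expr_percentile,
                "top_k": cfg.top_k,
                "seed": cfg.seed,
            },
        }

    classes = set(normalized.samples["tissue_class"])
    confounders = [
        c for c in (CLASS_BLADDER, CLASS_BC, CLASS_UTI) if c in classes
    ]
    contrasts: dict[str, pd.DataFrame] = {}
    candidates: list[pd.DataFrame] = []
    venn: dict[str, screen.VennResult] = {}
    with _stage("diffexpr"):
        for compartment, (disease, normal) in COMPARTMENTS.items():
            if disease not in classes:
                continue
            references = ([normal] if normal in classes else []) + confounders
            for ref in references:
                spec = ContrastSpec(disease, ref)
                contrasts[spec.name] = run_contrast(
                    normalized, spec, alpha=cfg.alpha, fc_min=cfg.fc_min
                )
                n_up = int((contrasts[spec.name]["deg"] == "up").sum())
                logger.info("contrast %s: %d up-DEGs", spec.name, n_up)

    with _stage("screen"):
        for compartment, (disease, normal) in COMPARTMENTS.items():
            if disease not in classes:
                continue
            if normal in classes and len(confounders) == 3:
                rule1 = screen.type1_rule(
                    disease, normal, CLASS_BLADDER, CLASS_BC, CLASS_UTI,
                    compartment=compartment,
                    percentile=cfg.low_expr_percentile, top_k=cfg.top_k,
                )
                candidates.append(
                    screen.select_candidates(contrasts, normalized, rule1)
                )
                up_sets = [
                    set(contrasts[n].index[contrasts[n]["deg"] == "up"])
                    for n in rule1.required_up
                ]
                venn[compartment] = screen.venn_codifferential(
                    up_sets, labels=list(rule1.required_up)
                )
            if len(confounders) == 3:
                rule2 = screen.type2_rule(
                    disease, CLASS_BLADDER, CLASS_BC, CLASS_UTI,
                    compartment=compartment,
                    percentile=cfg.low_expr_percentile, top_k=cfg.top_k,
                )
                candidates.append(
                    screen.select_candidates(contrasts, normalized, rule2)
                )

    table = (
        pd.concat(candidates, ignore_index=True)
        if candidates
        else pd.DataFrame(columns=["gene_id", "rule_type", "compartment"])
    )
    logger.info("screen: %d candidates", len(table))
    return ScreenResult(candidates=table, contrasts=contrasts, qc=qc, venn=venn)


def run_screen(cfg: RunConfig) -> ScreenResult:
    """File-based screen entry point: read inputs, run, write outputs."""
    if not cfg.expression_path or not cfg.samples_path:
        raise ConfigurationError(
            "expression_path and samples_path are required for run_screen"
        )
    m = io.read_expression_tsv(cfg.expression_path, cfg.samples_path)
    result = screen_pipeline(m, cfg)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.candidates.to_csv(
        outdir / "candidates.tsv", sep="\t", index=False, float_format="%.17g"
    )
    with open(outdir / "qc.json", "w", encoding="utf-8") as fh:
        json.dump(result.qc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for name, res in result.contrasts.items():
        res.to_csv(
            outdir / f"contrast_{name}.tsv", sep="\t",
            index_label="gene_id", float_format="%.17g",
        )
    return result


# ---------------------------------------------------------------------------
# clinical verification report
# ---------------------------------------------------------------------------

#: default ROC groupings: (name, test groups, control groups)
DEFAULT_ROC_GROUPS = [
    ("dm_vs_hc", ("NA", "MA", "OA"), ("HC",)),
    ("dm_vs_hc_uti_bc", ("NA", "MA", "OA"), ("HC", "UTI", "BC")),
]


def _marker_values(cohort: pd.DataFrame) -> pd.Series:
    """Relative expression per subject, recomputed from Ct columns when
    present, otherwise taken from the ``relative_expression`` column."""
    hk_cols = [c for c in cohort.columns if c.endswith("_ct") and c != "target_ct"]
    if "target_ct" in cohort.columns and hk_cols:
        return cohort.apply(
            lambda row: clinical.relative_expression(
                row["target_ct"], [row[c] for c in hk_cols]
            ),
            axis=1,
        )
    if "relative_expression" in cohort.columns:
        return cohort["relative_expression"].astype(float)
    raise ValidationError(
        "cohort needs either target_ct plus housekeeping *_ct columns or "
        "a relative_expression column"
    )


def clinical_report(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    roc_groups=None,
    control_group: str = "HC",
    correlation_exclude: tuple[str, ...] = ("ESKD",),
    dilution: pd.DataFrame | None = None,
    fold_decimals: int = 1,
) -> dict:
    """Verification statistics for one urinary marker in a cohort.

    Returns a JSON-serializable dict with per-group medians and IQRs,
    fold-of-medians versus the control group, Kruskal-Wallis and pairwise
    BH-adjusted rank-sum comparisons, Spearman correlations with clinical
    covariates (selected groups excluded, end-stage disease by default),
    ROC results per grouping, and CV reproducibility if a dilution series
    is supplied.
    """
    unknown = set(cohort["group"].unique()) - set(COHORT_GROUPS)
    if unknown:
        raise ValidationError(f"unknown group labels: {sorted(unknown)}")
    marker = _marker_values(cohort)
    groups_present = [g for g in COHORT_GROUPS if g in set(cohort["group"])]
    by_group = {
        g: marker[cohort["group"] == g].to_numpy(dtype=float)
        for g in groups_present
    }
    report: dict = {"groups": {}, "n_subjects": int(len(cohort))}
    for g, vals in by_group.items():
        report["groups"][g] = {
            "n": int(vals.size),
            "median": float(np.median(vals)),
            "iqr": [float(np.quantile(vals, 0.25)), float(np.quantile(vals, 0.75))],
        }

    if control_group in by_group:
        folds = {}
        for g, vals in by_group.items():
            if g == control_group:
                continue
            folds[g] = clinical.fold_of_medians(
                vals, by_group[control_group], decimals=fold_decimals
            )
        report["fold_of_medians_vs_" + control_group] = folds

    if len(by_group) >= 2:
        h, p = clinical.kruskal_wallis(list(by_group.values()))
        report["kruskal_wallis"] = {"h": h, "p": p}
        pairwise = clinical.pairwise_tests(by_group)
        report["pairwise"] = pairwise.to_dict(orient="records")
    else:
        report["kruskal_wallis"] = None
        report["pairwise"] = []

    if covariates is None:
        skip = {"subject_id", "group", "relative_expression", "target_ct"}
        covariates = [
            c for c in cohort.columns
            if c not in skip and not c.endswith("_ct")
            and pd.api.types.is_numeric_dtype(cohort[c])
        ]
    corr_mask = ~cohort["group"].isin(correlation_exclude)
    report["spearman"] = {}
    for cov in covariates:
        sub = cohort.loc[corr_mask, cov].astype(float)
        rho, p = clinical.spearman(
            marker[corr_mask].to_numpy(), sub.to_numpy()
        )
        report["spearman"][cov] = {"rho": rho, "p": p}

    if roc_groups is None:
        roc_groups = DEFAULT_ROC_GROUPS
    report["roc"] = {}
    for name, test_groups, control_groups in roc_groups:
        test_groups = [g for g in test_groups if g in by_group]
        control_groups = [g for g in control_groups if g in by_group]
        if not test_groups or not control_groups:
            continue
        mask = cohort["group"].isin(list(test_groups) + list(control_groups))
        labels = cohort.loc[mask, "group"].isin(test_groups).to_numpy()
        result = clinical.roc_analysis(marker[mask].to_numpy(), labels)
        report["roc"][name] = result.to_dict()

    if dilution is not None:
        cells, gene_avg = clinical.cv_report(dilution)
        report["cv"] = {
            "cells": cells.to_dict(orient="records"),
            "gene_average": {k: float(v) for k, v in gene_avg.items()},
        }
    return report


def run_clinical(cfg: RunConfig) -> dict:
    """File-based clinical entry point: read cohort (and optional dilution
    series), compute the report, write ``clinical_report.json``."""
    if not cfg.cohort_path:
        raise ConfigurationError("cohort_path is required for run_clinical")
    cohort = io.read_cohort_tsv(cfg.cohort_path)
    dilution = (
        io.read_dilution_tsv(cfg.dilution_path) if cfg.dilution_path else None
    )
    report = clinical_report(
        cohort, dilution=dilution, fold_decimals=cfg.fold_decimals
    )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "clinical_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
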