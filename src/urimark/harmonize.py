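"""Multi-platform pooling, normalization and array-level quality control.

The harmonization path mirrors how pooled expression-array compendia are
prepared: restrict to the feature space shared by all platforms, quantile
normalize, optionally summarize probe groups by Tukey median polish, then
screen for inconsistent datasets with relative log expression (RLE) and for
batch structure with principal components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import HarmonizationError, ValidationError

__all__ = [
    "intersect_platform_features",
    "split_by_platform",
    "quantile_normalize",
    "median_polish_summarize",
    "rle_screen",
    "array_qc_metrics",
    "pca_batch_score",
    "RleReport",
    "PcaBatchReport",
]


def split_by_platform(m: ExpressionMatrix) -> list[ExpressionMatrix]:
    """Split a pooled matrix into per-platform matrices, dropping features
    a platform does not carry (all-NaN within the platform's samples)."""
    out = []
    for platform in sorted(m.samples["platform"].unique()):
        ids = list(m.samples.index[m.samples["platform"] == platform])
        sub = m.subset_samples(ids)
        carried = sub.values.index[~sub.values.isna().all(axis=1)]
        out.append(sub.subset_genes(list(carried)))
    return out


def intersect_platform_features(
    matrices: list[ExpressionMatrix],
) -> ExpressionMatrix:
    """Pool matrices onto the intersection of their feature sets.

    Output features are the sorted intersection; samples are concatenated
    in input order with annotations preserved. An empty intersection raises
    :class:`HarmonizationError` reporting all pairwise overlap sizes.
    """
    if not matrices:
        raise ValidationError("need at least one input matrix")
    for m in matrices:
        if m.n_genes == 0:
            raise ValidationError("input matrix has no features")
    feature_sets = [set(m.values.index) for m in matrices]
    shared = set.intersection(*feature_sets)
    if not shared:
        overlaps = {
            f"{i}x{j}": len(feature_sets[i] & feature_sets[j])
            for i in range(len(feature_sets))
            for j in range(i + 1, len(feature_sets))
        }
        raise HarmonizationError(
            f"empty feature intersection; pairwise overlaps: {overlaps}"
        )
    ordered = sorted(shared)
    values = pd.concat([m.values.loc[ordered] for m in matrices], axis=1)
    samples = pd.concat([m.samples for m in matrices], axis=0)
    return ExpressionMatrix(values=values, samples=samples)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of sorted means.

    Each sample's sorted values are replaced by the across-sample mean of
    sorted values; within-sample ties receive the mean of the reference
    values at their tied ranks, so the result is deterministic and
    independent of input row order.
    """
    if m.n_samples < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    if m.has_missing():
        raise ValidationError("quantile normalization requires no missing values")
    x = m.values.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average reference values over tied ranks
        ser = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = ser.to_numpy()
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=values, samples=m.samples.copy())


def _polish_one(x: np.ndarray, max_iter: int, tol: float) -> np.ndarray:
    """Tukey median polish of one probe-by-sample block.

    Returns the per-sample summary ``overall + column effect``.
    """
    nr, nc = x.shape
    if nr == 1:
        return x[0].copy()
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    res = x.astype(float).copy()
    last = np.abs(res).sum()
    for _ in range(max_iter):
        rmed = np.median(res, axis=1)
        res -= rmed[:, None]
        row += rmed
        delta = np.median(col)
        col -= delta
        overall += delta
        cmed = np.median(res, axis=0)
        res -= cmed[None, :]
        col += cmed
        delta = np.median(row)
        row -= delta
        overall += delta
        total = np.abs(res).sum()
        if abs(last - total) < tol * max(total, 1.0):
            break
        last = total
    return overall + col


def median_polish_summarize(
    probe_values: pd.DataFrame,
    probe_to_gene: pd.Series,
    max_iter: int = 10,
    tol: float = 0.01,
) -> pd.DataFrame:
    """Summarize probe-level rows into one expression value per gene.

    ``probe_values`` is probes x samples; ``probe_to_gene`` maps each probe
    index label to its gene. Each gene's block is median-polished and the
    per-sample summary is overall + column effect (the robust analogue of
    a per-gene mean); single-probe genes pass through unchanged.
    """
    if not np.isfinite(probe_values.to_numpy(dtype=float)).all():
        raise ValidationError("median polish requires finite inputs")
    missing = probe_values.index.difference(probe_to_gene.index)
    if len(missing):
        raise ValidationError(f"probes without gene mapping: {list(missing[:5])}")
    genes = probe_to_gene.loc[probe_values.index]
    out = {}
    for gene, block in probe_values.groupby(genes.to_numpy()):
        out[gene] = _polish_one(
            block.to_numpy(dtype=float), max_iter=max_iter, tol=tol
        )
    summary = pd.DataFrame.from_dict(out, orient="index")
    summary.columns = probe_values.columns
    summary.index.name = "gene_id"
    return summary.sort_index()


@dataclass
class RleReport:
    """Relative-log-expression consistency screen."""

    per_sample: pd.DataFrame  # columns: rle_median, rle_iqr, dataset_id
    dataset_flags: dict[str, bool] = field(default_factory=dict)

    def flagged_datasets(self) -> list[str]:
        return sorted(d for d, f in self.dataset_flags.items() if f)


def rle_screen(m: ExpressionMatrix, bias_threshold: float = 0.15) -> RleReport:
    """Flag datasets whose arrays sit systematically off the compendium.

    RLE(g, s) = value - across-sample median of gene g. A dataset is
    flagged when the median of its samples' absolute RLE medians exceeds
    ``bias_threshold`` (log2 units).
    """
    if m.n_samples < 2:
        raise ValidationError("RLE screen needs >= 2 samples")
    rle = m.values.sub(m.values.median(axis=1), axis=0)
    med = rle.median(axis=0)
    iqr = rle.quantile(0.75, axis=0) - rle.quantile(0.25, axis=0)
    per_sample = pd.DataFrame(
        {
            "rle_median": med,
            "rle_iqr": iqr,
            "dataset_id": m.samples["dataset_id"],
        }
    )
    flags = {}
    for dataset, grp in per_sample.groupby("dataset_id"):
        flags[str(dataset)] = bool(
            np.median(np.abs(grp["rle_median"].to_numpy())) > bias_threshold
        )
    return RleReport(per_sample=per_sample, dataset_flags=flags)


def array_qc_metrics(
    m: ExpressionMatrix, detect_threshold: float = 5.0
) -> pd.DataFrame:
    """Matrix-level per-array QC proxies.

    Scale factor = (median of per-sample trimmed means, linear scale, 2%
    trim each tail) / per-sample trimmed mean — the factor by which an
    array would be rescaled to the common target. Fraction-detected = share
    of features above ``detect_threshold`` (log2).
    """
    if m.n_samples < 1:
        raise ValidationError("QC metrics need >= 1 sample")
    linear = np.power(2.0, m.values.to_numpy(dtype=float))
    tmeans = stats.trim_mean(linear, 0.02, axis=0)
    target = float(np.median(tmeans))
    frac = (m.values.to_numpy(dtype=float) > detect_threshold).mean(axis=0)
    return pd.DataFrame(
        {
            "scale_factor": target / tmeans,
            "fraction_detected": frac,
        },
        index=m.values.columns,
    )


@dataclass
class PcaBatchReport:
    """Per-PC variance decomposition against batch and biology labels.

    ``batch_r2_within`` is the between-dataset R^2 after removing
    tissue-class means from the PC scores; because datasets are usually
    nested within tissue classes, the raw between-dataset R^2 is always at
    least the biology R^2 and only the within-class component isolates
    true batch structure.
    """

    pc_variance_ratio: np.ndarray
    batch_r2: np.ndarray
    biology_r2: np.ndarray
    batch_r2_within: np.ndarray
    batch_flag: bool


def _group_r2(scores: np.ndarray, labels: np.ndarray) -> float:
    """Between-group sum of squares / total sum of squares of PC scores."""
    total = float(((scores - scores.mean()) ** 2).sum())
    if total == 0.0 or len(np.unique(labels)) < 2:
        return 0.0
    between = 0.0
    for lab in np.unique(labels):
        sel = scores[labels == lab]
        between += len(sel) * (sel.mean() - scores.mean()) ** 2
    return float(between / total)


def pca_batch_score(
    m: ExpressionMatrix,
    n_pcs: int = 2,
    batch_r2_threshold: float = 0.5,
) -> PcaBatchReport:
    """Detect batch structure among the leading principal components.

    Genes are mean-centered and the sample scores of the first ``n_pcs``
    PCs are decomposed into between-group variance fractions (R^2) for the
    dataset grouping and the tissue-class grouping. The batch flag is
    raised when some PC is dominated by dataset structure beyond what the
    biology explains: the within-class batch R^2 exceeds the threshold and
    the raw batch R^2 exceeds that PC's biology R^2.
    """
    if m.n_samples < 3:
        raise ValidationError("PCA batch score needs >= 3 samples")
    if n_pcs > m.n_samples:
        raise ValidationError("n_pcs exceeds sample count")
    if n_pcs > m.n_genes:
        raise ValidationError("n_pcs exceeds feature count")
    x = m.values.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_pcs, len(s))
    scores = s[:k, None] * vt[:k]  # k x samples
    var_ratio = (s[:k] ** 2) / max((s**2).sum(), np.finfo(float).tiny)
    datasets = m.samples["dataset_id"].to_numpy()
    classes = m.samples["tissue_class"].to_numpy()
    batch_r2 = np.array([_group_r2(scores[i], datasets) for i in range(k)])
    bio_r2 = np.array([_group_r2(scores[i], classes) for i in range(k)])
    # residualize scores on class means, then ask how much of what is left
    # the dataset labels explain
    within = np.empty(k)
    for i in range(k):
        resid = scores[i].astype(float).copy()
        for lab in np.unique(classes):
            sel = classes == lab
            resid[sel] -= resid[sel].mean()
        within[i] = _group_r2(resid, datasets)
    flag = bool(
        np.any((within > batch_r2_threshold) & (batch_r2 > bio_r2))
    )
    return PcaBatchReport(
        pc_variance_ratio=var_ratio,
        batch_r2=batch_r2,
        biology_r2=bio_r2,
        batch_r2_within=within,
        batch_flag=flag,
    )
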