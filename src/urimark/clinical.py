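"""Clinical verification statistics for qPCR-measured urinary markers.

Covers the stage-1/stage-2 analyses: delta-Ct relative quantification
against housekeeping transcripts, fold changes of group medians,
Kruskal-Wallis and pairwise rank-sum comparisons with Benjamini-Hochberg
adjustment, Spearman correlation with clinical covariates, ROC analysis
with the Youden-index optimal cutoff, and replicate coefficient-of-
variation (CV) summaries for assay reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import ValidationError

__all__ = [
    "round_half_up",
    "relative_expression",
    "fold_of_medians",
    "kruskal_wallis",
    "pairwise_tests",
    "spearman",
    "RocResult",
    "roc_analysis",
    "auc_band",
    "cv_report",
    "average_cv",
]


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (the convention of printed clinical tables;
    banker's rounding would send e.g. 0.125 to 0.12)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def relative_expression(
    target_ct: float, housekeeping_cts: Sequence[float] | float
) -> float:
    """Linear relative expression 2^-(target Ct - mean housekeeping Ct).

    With several housekeeping genes the reference is the arithmetic mean
    of their Cts, i.e. the geometric mean on the linear scale.
    """
    if np.isscalar(housekeeping_cts):
        hk = [float(housekeeping_cts)]  # type: ignore[arg-type]
    else:
        hk = [float(v) for v in housekeeping_cts]  # type: ignore[union-attr]
    if not hk:
        raise ValidationError("need >= 1 housekeeping Ct")
    values = [float(target_ct), *hk]
    if not all(math.isfinite(v) for v in values):
        raise ValidationError("Ct values must be finite")
    return float(2.0 ** -(float(target_ct) - sum(hk) / len(hk)))


def fold_of_medians(
    test: Iterable[float], control: Iterable[float], decimals: int = 1
) -> float:
    """median(test) / median(control), rounded half-up to ``decimals``."""
    test = np.asarray(list(test), dtype=float)
    control = np.asarray(list(control), dtype=float)
    if test.size == 0 or control.size == 0:
        raise ValidationError("both samples must be non-empty")
    ctrl_med = float(np.median(control))
    if ctrl_med <= 0:
        raise ValidationError("control median must be > 0")
    return round_half_up(float(np.median(test)) / ctrl_med, decimals)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square(k-1) p-value.

    The fully degenerate input (every value identical across all groups)
    returns (0, 1) by convention so that constant fixtures do not crash
    the pipeline.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def pairwise_tests(
    groups: dict[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Two-sided rank-sum (Mann-Whitney) tests for each group pair.

    Uses the normal approximation with tie and continuity correction;
    adjusted p-values are BH across the tested pair family (all pairs by
    default).
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    if pairs is None:
        pairs = list(combinations(sorted(groups), 2))
    rows = []
    for a, b in pairs:
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if xa.size == 0 or xb.size == 0:
            raise ValidationError(f"empty group in pair ({a!r}, {b!r})")
        pooled = np.concatenate([xa, xb])
        if np.all(pooled == pooled[0]):
            u, p = float(xa.size * xb.size) / 2.0, 1.0
        else:
            res = stats.mannwhitneyu(
                xa, xb, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            )
            u, p = float(res.statistic), float(res.pvalue)
        rows.append({"group_a": a, "group_b": b, "u": u, "p": p})
    table = pd.DataFrame(rows)
    table["padj"] = bh_adjust(table["p"].to_numpy())
    return table


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need equal-length inputs with n >= 3")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def auc_band(auc: float) -> str:
    """Qualitative discrimination band for an AUC value."""
    if auc > 0.9:
        return "excellent"
    if auc > 0.8:
        return "good"
    if auc > 0.7:
        return "moderate"
    if auc > 0.6:
        return "poor"
    return "below-poor"


@dataclass
class RocResult:
    auc: float
    auc_p: float
    cutoff: float
    sensitivity: float
    specificity: float
    band: str
    n_positive: int
    n_negative: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_p": self.auc_p,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "band": self.band,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[bool],
    positive_is_high: bool = True,
) -> RocResult:
    """Empirical ROC curve, trapezoid AUC and Youden-index optimal cutoff.

    The trapezoid AUC over all observed thresholds equals the rank-sum
    statistic U/(n1*n0) with ties counted one half. The AUC p-value uses
    the tie-corrected normal approximation to the rank-sum null. The
    optimal cutoff maximizes sensitivity + specificity; ties prefer higher
    sensitivity, then the lower cutoff value. A subject is called positive
    when score >= cutoff (<= cutoff when ``positive_is_high`` is False).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.size != y.size:
        raise ValidationError("scores and labels must have equal length")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    oriented = s if positive_is_high else -s

    thresholds = np.unique(oriented)[::-1]  # descending
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = oriented >= t
        tpr[i] = (pred & y).sum() / n1
        fpr[i] = (pred & ~y).sum() / n0
    # prepend the (0, 0) corner (threshold above every score)
    tpr_full = np.concatenate([[0.0], tpr])
    fpr_full = np.concatenate([[0.0], fpr])
    auc = float(np.trapezoid(tpr_full, fpr_full))

    # rank-sum normal approximation for the AUC p-value
    n = n1 + n0
    _, counts = np.unique(oriented, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    u = auc * n1 * n0
    if var_u <= 0:
        auc_p = 1.0
    else:
        z = (u - n1 * n0 / 2.0) / math.sqrt(var_u)
        auc_p = float(2.0 * stats.norm.sf(abs(z)))

    youden = tpr + (1.0 - fpr)
    # ascending lexsort keys: maximize Youden, then sensitivity, then
    # prefer the lower cutoff on the original score scale
    cutoff_key = thresholds if positive_is_high else -thresholds
    best = np.lexsort((cutoff_key, -tpr, -youden))[0]
    cutoff = float(thresholds[best] if positive_is_high else -thresholds[best])
    return RocResult(
        auc=auc,
        auc_p=auc_p,
        cutoff=cutoff,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        band=auc_band(auc),
        n_positive=n1,
        n_negative=n0,
    )


def cv_report(
    dilution: pd.DataFrame, sd_mode: str = "population"
) -> tuple[pd.DataFrame, pd.Series]:
    """Replicate coefficient of variation per gene and input amount.

    CV = sigma / mu expressed as a percent, rounded half-up to 2 decimals;
    sigma uses the n-denominator ("population") by default, with
    ``sd_mode="sample"`` for the n-1 convention. The per-gene average CV
    is the arithmetic mean of the (rounded) per-amount CVs, rounded to 2
    decimals — the convention under which printed per-gene averages arise
    from printed per-dilution values.

    Returns (per-cell table, per-gene average CV series).
    """
    if sd_mode not in ("population", "sample"):
        raise ValidationError("sd_mode must be 'population' or 'sample'")
    required = {"gene", "amount_ng", "replicate", "ct"}
    missing = required - set(dilution.columns)
    if missing:
        raise ValidationError(f"dilution table lacks columns: {sorted(missing)}")
    ddof = 0 if sd_mode == "population" else 1
    rows = []
    for (gene, amount), grp in dilution.groupby(
        ["gene", "amount_ng"], sort=True
    ):
        cts = grp["ct"].to_numpy(dtype=float)
        if cts.size < 2:
            raise ValidationError(
                f"gene {gene!r} at {amount} ng has < 2 replicates"
            )
        mu = float(cts.mean())
        sigma = float(cts.std(ddof=ddof))
        rows.append(
            {
                "gene": gene,
                "amount_ng": float(amount),
                "n_replicates": int(cts.size),
                "mean_ct": mu,
                "sd_ct": sigma,
                "cv_pct": round_half_up(sigma / mu * 100.0, 2),
            }
        )
    cells = pd.DataFrame(rows).sort_values(
        ["gene", "amount_ng"], ascending=[True, False], ignore_index=True
    )
    gene_avg = cells.groupby("gene")["cv_pct"].apply(
        lambda v: average_cv(v.to_numpy())
    )
    gene_avg.name = "average_cv_pct"
    return cells, gene_avg


def average_cv(cv_values: Iterable[float], decimals: int = 2) -> float:
    """Arithmetic mean of per-dilution CV percentages, rounded half-up."""
    values = np.asarray(list(cv_values), dtype=float)
    if values.size == 0:
        raise ValidationError("need >= 1 CV value")
    return round_half_up(float(values.mean()), decimals)
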