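"""Two-rule cross-tissue selection of urinary kidney-specific candidates.

A candidate urinary marker of kidney disease must be (type 1) up-regulated
in diseased kidney tissue relative to normal kidney *and* to every
confounding urinary cell source (bladder, bladder cancer, UTI leukocytes),
with constitutively low expression in those confounder tissues; or
(type 2) up-regulated relative to all confounder sources with low
expression in bladder cancer and leukocytes, ranked by the disease-vs-
bladder fold change. Both rules run per kidney compartment (glomeruli,
tubules).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import ScreeningError, ValidationError

__all__ = [
    "VennResult",
    "venn_codifferential",
    "low_expression_filter",
    "ScreenRule",
    "type1_rule",
    "type2_rule",
    "select_candidates",
]


@dataclass
class VennResult:
    """Exact Venn decomposition of several gene sets."""

    labels: list[str]
    intersection: set[str]
    #: region mask (e.g. "1101", aligned with labels) -> exclusive count
    region_counts: dict[str, int] = field(default_factory=dict)


def venn_codifferential(
    deg_sets: Sequence[Iterable[str]],
    labels: Sequence[str] | None = None,
) -> VennResult:
    """Full intersection plus exclusive counts for every Venn region.

    For n input sets all 2^n - 1 non-empty membership patterns are counted
    by exact set arithmetic over the union.
    """
    sets = [set(s) for s in deg_sets]
    if len(sets) < 2:
        raise ValidationError("need >= 2 DEG sets")
    if labels is None:
        labels = [f"set{i + 1}" for i in range(len(sets))]
    if len(labels) != len(sets):
        raise ValidationError("labels length must match number of sets")
    n = len(sets)
    counts = {
        "".join(str(b) for b in mask): 0
        for mask in product((0, 1), repeat=n)
        if any(mask)
    }
    for element in set.union(*sets):
        mask = "".join("1" if element in s else "0" for s in sets)
        counts[mask] += 1
    return VennResult(
        labels=list(labels),
        intersection=set.intersection(*sets),
        region_counts=counts,
    )


def low_expression_filter(
    m: ExpressionMatrix,
    genes: Iterable[str],
    confounder_classes: Sequence[str],
    percentile: float = 25.0,
) -> pd.DataFrame:
    """Flag genes constitutively low in each confounder tissue class.

    A gene passes for a class when its mean log2 expression across that
    class's samples lies below the given percentile of all genes' class
    means. Overall pass requires passing in every listed class.
    ``percentile=100`` disables the filter (every gene passes, including
    the class maximum).
    """
    if not 0.0 < percentile <= 100.0:
        raise ValidationError("percentile must be in (0, 100]")
    genes = list(genes)
    unknown_genes = set(genes) - set(m.values.index)
    if unknown_genes:
        raise ValidationError(f"unknown genes: {sorted(unknown_genes)[:5]}")
    available = set(m.samples["tissue_class"])
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for cls in confounder_classes:
        if cls not in available:
            raise ValidationError(f"unknown tissue class {cls!r}")
        if percentile == 100.0:
            out[f"low_in_{cls}"] = True
            continue
        cls_means = m.values[m.samples_in_class(cls)].mean(axis=1)
        cutoff = np.percentile(cls_means.to_numpy(dtype=float), percentile)
        out[f"low_in_{cls}"] = cls_means.loc[genes].to_numpy() < cutoff
    out["pass"] = out.all(axis=1) if len(confounder_classes) else True
    return out


@dataclass(frozen=True)
class ScreenRule:
    """One candidate-selection rule.

    ``required_up`` names the contrasts in which a candidate must be an
    up-called DEG; ``rank_contrast`` supplies the fold change used for
    ranking; the low-expression filter runs on ``confounder_classes`` at
    ``percentile``. Only the top ``top_k`` candidates are kept.
    """

    rule_type: str
    compartment: str
    required_up: tuple[str, ...]
    rank_contrast: str
    confounder_classes: tuple[str, ...]
    percentile: float = 25.0
    top_k: int = 8

    def __post_init__(self) -> None:
        if self.rule_type not in ("type1", "type2"):
            raise ValidationError("rule_type must be 'type1' or 'type2'")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if not 0.0 < self.percentile <= 100.0:
            raise ValidationError("percentile must be in (0, 100]")
        if self.rank_contrast not in self.required_up:
            raise ValidationError("rank_contrast must be a required contrast")


def type1_rule(
    disease_class: str,
    normal_class: str,
    bladder_class: str,
    bc_class: str,
    uti_class: str,
    compartment: str,
    percentile: float = 25.0,
    top_k: int = 8,
) -> ScreenRule:
    """Disease-vs-normal-kidney rule: up in all four contrasts, low in all
    three confounder tissues, ranked by the disease-vs-normal fold change."""
    vs = lambda ref: f"{disease_class}_vs_{ref}"  # noqa: E731
    return ScreenRule(
        rule_type="type1",
        compartment=compartment,
        required_up=(
            vs(normal_class), vs(bladder_class), vs(bc_class), vs(uti_class),
        ),
        rank_contrast=vs(normal_class),
        confounder_classes=(bladder_class, bc_class, uti_class),
        percentile=percentile,
        top_k=top_k,
    )


def type2_rule(
    disease_class: str,
    bladder_class: str,
    bc_class: str,
    uti_class: str,
    compartment: str,
    percentile: float = 25.0,
    top_k: int = 8,
) -> ScreenRule:
    """Disease-vs-bladder rule: up versus all confounder sources, low in
    bladder cancer and leukocytes, ranked by the disease-vs-bladder fold
    change."""
    vs = lambda ref: f"{disease_class}_vs_{ref}"  # noqa: E731
    return ScreenRule(
        rule_type="type2",
        compartment=compartment,
        required_up=(vs(bladder_class), vs(bc_class), vs(uti_class)),
        rank_contrast=vs(bladder_class),
        confounder_classes=(bc_class, uti_class),
        percentile=percentile,
        top_k=top_k,
    )


def select_candidates(
    results: Mapping[str, pd.DataFrame],
    m: ExpressionMatrix,
    rule: ScreenRule,
) -> pd.DataFrame:
    """Apply one screening rule to per-contrast moderated-t results.

    Candidates are genes called 'up' in every required contrast that pass
    the low-expression filter, ranked by the rank contrast's log2 fold
    change (descending, ties broken by gene ID) and truncated to
    ``top_k``. Returns an empty table (same columns) when nothing passes.
    """
    for name in rule.required_up:
        if name not in results:
            raise ScreeningError(f"missing contrast result {name!r}")
    up_sets = [
        set(res.index[res["deg"] == "up"])
        for res in (results[name] for name in rule.required_up)
    ]
    shared = sorted(set.intersection(*up_sets)) if up_sets else []

    columns = (
        ["gene_id", "rule_type", "compartment", "rank_log2fc", "rank_fc"]
        + [f"up_in_{name}" for name in rule.required_up]
        + [f"low_in_{cls}" for cls in rule.confounder_classes]
    )
    if not shared:
        return pd.DataFrame(columns=columns)

    filt = low_expression_filter(
        m, shared, list(rule.confounder_classes), rule.percentile
    )
    passed = [g for g in shared if bool(filt.loc[g, "pass"])]
    if not passed:
        return pd.DataFrame(columns=columns)

    rank_fc = results[rule.rank_contrast].loc[passed, "log2fc"]
    table = pd.DataFrame(
        {
            "gene_id": passed,
            "rule_type": rule.rule_type,
            "compartment": rule.compartment,
            "rank_log2fc": rank_fc.to_numpy(dtype=float),
        }
    )
    table["rank_fc"] = 2.0 ** table["rank_log2fc"]
    for name in rule.required_up:
        table[f"up_in_{name}"] = True
    for cls in rule.confounder_classes:
        table[f"low_in_{cls}"] = filt.loc[passed, f"low_in_{cls}"].to_numpy()
    table = table.sort_values(
        ["rank_log2fc", "gene_id"], ascending=[False, True], kind="mergesort"
    ).head(rule.top_k)
    return table.reset_index(drop=True)[columns]
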