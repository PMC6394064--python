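"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

#: Sample-sheet columns every ExpressionMatrix must carry.
SAMPLE_SHEET_COLUMNS = ("tissue_class", "dataset_id", "platform")

# Canonical tissue-class labels used by the screening rules.
CLASS_DKD_GLOM = "dkd_glomeruli"
CLASS_NORMAL_GLOM = "normal_glomeruli"
CLASS_DKD_TUB = "dkd_tubules"
CLASS_NORMAL_TUB = "normal_tubules"
CLASS_BLADDER = "bladder"
CLASS_BC = "bladder_cancer"
CLASS_UTI = "uti_leukocytes"

#: Clinical cohort group vocabulary (healthy controls, normoalbuminuric
#: diabetes, micro-/overt albuminuria, end-stage kidney disease, urinary
#: tract infection, bladder cancer).
COHORT_GROUPS = ("HC", "NA", "MA", "OA", "ESKD", "UTI", "BC")


@dataclass
class ExpressionMatrix:
    """A log2-scale genes x samples expression matrix with sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene/feature ID with one column per sample,
        log2 intensities. NaN marks features not carried by a sample's
        platform; NaNs are only permitted before harmonization.
    samples
        Sample sheet indexed by sample ID with columns ``tissue_class``,
        ``dataset_id`` and ``platform``, in the same order as the value
        columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature IDs: {list(dupes[:5])}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample IDs in expression matrix")
        if self.samples.index.has_duplicates:
            raise ValidationError("duplicate sample IDs in sample sheet")
        if list(self.values.columns) != list(self.samples.index):
            raise ValidationError(
                "sample sheet does not match expression matrix columns"
            )
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample sheet lacks columns: {missing}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def classes(self) -> list[str]:
        return sorted(self.samples["tissue_class"].unique())

    def samples_in_class(self, tissue_class: str) -> list[str]:
        mask = self.samples["tissue_class"] == tissue_class
        return list(self.samples.index[mask])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values[sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
        )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[gene_ids].copy(), samples=self.samples.copy()
        )

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())


@dataclass
class PlantedTruth:
    """Ground truth recorded by the compendium simulator.

    Attributes
    ----------
    signatures
        Mapping signature name -> list of gene IDs planted in it.
    signature_specs
        Mapping signature name -> dict with target_classes, log2_effect,
        baseline_offset.
    batch_shifts
        Mapping dataset ID -> additive log2 shift applied to that dataset.
    gene_variance
        Per-gene true residual variance (log2^2 units).
    platform_features
        Mapping platform label -> list of gene IDs carried by the platform.
    """

    signatures: dict[str, list[str]] = field(default_factory=dict)
    signature_specs: dict[str, dict] = field(default_factory=dict)
    batch_shifts: dict[str, float] = field(default_factory=dict)
    gene_variance: dict[str, float] = field(default_factory=dict)
    platform_features: dict[str, list[str]] = field(default_factory=dict)

    def planted_genes(self, signature: str) -> set[str]:
        return set(self.signatures[signature])

    def all_planted(self) -> set[str]:
        out: set[str] = set()
        for genes in self.signatures.values():
            out |= set(genes)
        return out

    def to_dict(self) -> dict:
        return {
            "signatures": self.signatures,
            "signature_specs": self.signature_specs,
            "batch_shifts": self.batch_shifts,
            "gene_variance": self.gene_variance,
            "platform_features": self.platform_features,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        return cls(
            signatures={k: list(v) for k, v in d.get("signatures", {}).items()},
            signature_specs=dict(d.get("signature_specs", {})),
            batch_shifts={k: float(v) for k, v in d.get("batch_shifts", {}).items()},
            gene_variance={
                k: float(v) for k, v in d.get("gene_variance", {}).items()
            },
            platform_features={
                k: list(v) for k, v in d.get("platform_features", {}).items()
            },
        )
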