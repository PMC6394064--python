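"""Synthetic data generators with known planted truth.

Three generators emulate the structure of a multi-tissue biomarker study:

* :func:`simulate_compendium` — a pooled multi-dataset, multi-platform
  microarray compendium on the log2 scale with additive per-dataset batch
  shifts, gene-wise variances drawn from a scaled inverse-chi-square prior
  (the same model the empirical-Bayes moderated t assumes downstream), and
  planted tissue-specific up-regulated gene signatures.
* :func:`simulate_cohort` — subject-level clinical cohorts with group-wise
  log-normal marker distributions and covariates coupled to the marker
  through a Gaussian copula at configured Spearman rank correlations.
* :func:`simulate_dilution_series` — qPCR dilution-series Ct triplicates
  with a linear response in log10(input RNA).

All randomness flows from a single integer seed expanded into independent
per-component substreams, so regenerating any component with the same seed
is byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CLASS_BC,
    CLASS_BLADDER,
    CLASS_DKD_GLOM,
    CLASS_DKD_TUB,
    CLASS_NORMAL_GLOM,
    CLASS_NORMAL_TUB,
    CLASS_UTI,
    ExpressionMatrix,
    PlantedTruth,
)
from .errors import ConfigurationError

__all__ = [
    "PlantedSignature",
    "CompendiumConfig",
    "CohortConfig",
    "DilutionConfig",
    "simulate_compendium",
    "simulate_cohort",
    "simulate_dilution_series",
    "default_screen_config",
    "stage1_cohort_config",
    "stage2_cohort_config",
]


# ---------------------------------------------------------------------------
# compendium
# ---------------------------------------------------------------------------


@dataclass
class PlantedSignature:
    """A planted gene signature.

    ``log2_effect`` is added in ``target_classes`` only; ``baseline_offset``
    is added in *every* class, which is how tissue-specific genes are made
    constitutively low outside their tissue of origin.
    """

    n_genes: int
    target_classes: tuple[str, ...]
    log2_effect: float
    baseline_offset: float = 0.0


@dataclass
class CompendiumConfig:
    """Configuration for the multi-tissue compendium simulator.

    Parameters
    ----------
    n_genes
        Total number of features.
    tissue_classes
        Class labels; one block of datasets is generated per class.
    datasets_per_class, samples_per_dataset
        Balanced design used for every class not listed in ``class_design``.
    class_design
        Optional per-class override mapping class -> (n_datasets,
        samples_per_dataset), for unbalanced case mixes.
    platforms
        Sequence of (platform label, fraction of features carried).
        Datasets are assigned to platforms round-robin. Features absent on
        a platform are emitted as missing values (NaN), never zeros.
    batch_shift_sd
        SD of the additive per-dataset shift, log2 units.
    prior_d0, prior_s0sq
        Parameters of the scaled inverse-chi-square variance prior: each
        gene's residual variance is drawn once as s0^2 * d0 / chi2(d0).
        ``prior_s0sq = 0`` gives the exact zero-noise limit.
    planted_sets
        Mapping signature name -> :class:`PlantedSignature`. Signatures are
        assigned disjoint gene blocks; planted genes are always carried by
        every platform (candidate genes can only come from the shared
        feature space, so planting them off-platform would make recovery
        ill-defined).
    baseline_mean
        Common baseline log2 intensity.
    seed
        Master seed; expanded into independent substreams.
    """

    n_genes: int = 2000
    tissue_classes: tuple[str, ...] = (
        CLASS_DKD_GLOM,
        CLASS_NORMAL_GLOM,
        CLASS_BLADDER,
        CLASS_BC,
        CLASS_UTI,
    )
    datasets_per_class: int = 3
    samples_per_dataset: int = 4
    class_design: dict[str, tuple[int, int]] = field(default_factory=dict)
    platforms: tuple[tuple[str, float], ...] = (("u133plus2", 1.0),)
    batch_shift_sd: float = 0.3
    prior_d0: float = 4.0
    prior_s0sq: float = 0.05
    planted_sets: dict[str, PlantedSignature] = field(default_factory=dict)
    baseline_mean: float = 8.0
    seed: int = 0


def _validate_compendium(cfg: CompendiumConfig) -> None:
    if cfg.n_genes <= 0:
        raise ConfigurationError("n_genes must be > 0")
    if not cfg.tissue_classes:
        raise ConfigurationError("tissue_classes must be non-empty")
    if len(set(cfg.tissue_classes)) != len(cfg.tissue_classes):
        raise ConfigurationError("tissue_classes must be unique")
    if cfg.datasets_per_class <= 0:
        raise ConfigurationError("datasets_per_class must be > 0")
    if cfg.samples_per_dataset <= 0:
        raise ConfigurationError("samples_per_dataset must be > 0")
    for cls, (nd, ns) in cfg.class_design.items():
        if cls not in cfg.tissue_classes:
            raise ConfigurationError(f"class_design references unknown class {cls!r}")
        if nd <= 0 or ns <= 0:
            raise ConfigurationError(f"class_design for {cls!r} must be positive")
    if not cfg.platforms:
        raise ConfigurationError("platforms must be non-empty")
    for label, frac in cfg.platforms:
        if not (0.0 < frac <= 1.0):
            raise ConfigurationError(
                f"platform {label!r} fraction must be in (0, 1], got {frac}"
            )
    if cfg.batch_shift_sd < 0:
        raise ConfigurationError("batch_shift_sd must be >= 0")
    if cfg.prior_d0 <= 0:
        raise ConfigurationError("prior_d0 must be > 0")
    if cfg.prior_s0sq < 0:
        raise ConfigurationError("prior_s0sq must be >= 0")
    n_planted = sum(s.n_genes for s in cfg.planted_sets.values())
    if n_planted > cfg.n_genes:
        raise ConfigurationError("planted_sets request more genes than n_genes")
    for name, sig in cfg.planted_sets.items():
        if sig.n_genes <= 0:
            raise ConfigurationError(f"planted set {name!r}: n_genes must be > 0")
        if not math.isfinite(sig.log2_effect) or not math.isfinite(
            sig.baseline_offset
        ):
            raise ConfigurationError(f"planted set {name!r}: effects must be finite")
        unknown = set(sig.target_classes) - set(cfg.tissue_classes)
        if unknown:
            raise ConfigurationError(
                f"planted set {name!r} targets unknown classes {sorted(unknown)}"
            )


def _class_design(cfg: CompendiumConfig, cls: str) -> tuple[int, int]:
    return cfg.class_design.get(
        cls, (cfg.datasets_per_class, cfg.samples_per_dataset)
    )


def simulate_compendium(
    cfg: CompendiumConfig,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Simulate a pooled multi-platform expression compendium.

    Each matrix entry is ``baseline + signature baseline offset + signature
    effect (sample in a target class) + dataset batch shift + N(0, var_g)``,
    with ``var_g`` drawn once per gene from the scaled inverse-chi-square
    prior. Features a sample's platform does not carry are NaN.

    Returns the matrix plus a :class:`PlantedTruth` recording every draw.
    """
    _validate_compendium(cfg)
    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_assign = np.random.default_rng(streams[0])
    rng_var = np.random.default_rng(streams[1])
    rng_batch = np.random.default_rng(streams[2])
    rng_noise = np.random.default_rng(streams[3])
    rng_platform = np.random.default_rng(streams[4])

    width = max(5, len(str(cfg.n_genes)))
    gene_ids = np.array([f"G{i:0{width}d}" for i in range(1, cfg.n_genes + 1)])

    # disjoint signature gene blocks from one permutation
    perm = rng_assign.permutation(cfg.n_genes)
    truth = PlantedTruth()
    offset_by_gene = np.zeros(cfg.n_genes)
    effect = {cls: np.zeros(cfg.n_genes) for cls in cfg.tissue_classes}
    pos = 0
    for name, sig in cfg.planted_sets.items():
        idx = perm[pos : pos + sig.n_genes]
        pos += sig.n_genes
        truth.signatures[name] = sorted(gene_ids[idx])
        truth.signature_specs[name] = {
            "target_classes": list(sig.target_classes),
            "log2_effect": sig.log2_effect,
            "baseline_offset": sig.baseline_offset,
        }
        offset_by_gene[idx] += sig.baseline_offset
        for cls in sig.target_classes:
            effect[cls][idx] += sig.log2_effect
    planted_idx = perm[:pos]

    # gene-wise true variances: s0^2 * d0 / chi2(d0)
    if cfg.prior_s0sq == 0.0:
        var_g = np.zeros(cfg.n_genes)
    else:
        var_g = cfg.prior_s0sq * cfg.prior_d0 / rng_var.chisquare(
            cfg.prior_d0, size=cfg.n_genes
        )
    truth.gene_variance = dict(zip(gene_ids, var_g.astype(float)))

    # platform feature subsets: planted genes always carried
    non_planted = np.setdiff1d(np.arange(cfg.n_genes), planted_idx)
    for label, frac in cfg.platforms:
        n_carry = int(round(frac * cfg.n_genes))
        n_carry = max(n_carry, len(planted_idx))
        extra = rng_platform.permutation(non_planted)[: n_carry - len(planted_idx)]
        carried = np.sort(np.concatenate([planted_idx, extra]))
        truth.platform_features[label] = sorted(gene_ids[carried])

    columns: list[np.ndarray] = []
    sample_rows: list[dict] = []
    platform_labels = [p[0] for p in cfg.platforms]
    plat_counter = 0
    for cls in cfg.tissue_classes:
        n_datasets, n_samples = _class_design(cfg, cls)
        for d in range(1, n_datasets + 1):
            dataset_id = f"{cls}.d{d}"
            platform = platform_labels[plat_counter % len(platform_labels)]
            plat_counter += 1
            shift = float(rng_batch.normal(0.0, cfg.batch_shift_sd))
            truth.batch_shifts[dataset_id] = shift
            carried = np.isin(gene_ids, truth.platform_features[platform])
            mean_vec = (
                cfg.baseline_mean + offset_by_gene + effect[cls] + shift
            )
            for s in range(1, n_samples + 1):
                noise = rng_noise.normal(0.0, 1.0, cfg.n_genes) * np.sqrt(var_g)
                col = mean_vec + noise
                col = np.where(carried, col, np.nan)
                columns.append(col)
                sample_rows.append(
                    {
                        "sample_id": f"{dataset_id}.s{s}",
                        "tissue_class": cls,
                        "dataset_id": dataset_id,
                        "platform": platform,
                    }
                )

    values = pd.DataFrame(
        np.column_stack(columns),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[r["sample_id"] for r in sample_rows],
    )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    return ExpressionMatrix(values=values, samples=samples), truth


def default_screen_config(seed: int = 0, n_genes: int = 2000) -> CompendiumConfig:
    """The packaged glomerular screening fixture.

    2000 genes across the five screening classes with a case mix mirroring
    a pooled compendium of 7/40/23/19/5 arrays (disease glomeruli, normal
    glomeruli, bladder, bladder cancer, UTI leukocytes), two platforms
    sharing 80% of features, and three planted signatures: 20
    kidney-disease-specific genes (up 2 log2 units in disease glomeruli,
    constitutively low elsewhere) plus 30-gene bladder-high and
    leukocyte-high confounder sets. The residual batch scale (0.05 log2,
    below the default RLE discard threshold) models a compendium whose
    grossly biased datasets have already been discarded by QC.
    """
    return CompendiumConfig(
        n_genes=n_genes,
        tissue_classes=(
            CLASS_DKD_GLOM,
            CLASS_NORMAL_GLOM,
            CLASS_BLADDER,
            CLASS_BC,
            CLASS_UTI,
        ),
        class_design={
            CLASS_DKD_GLOM: (2, 4),
            CLASS_NORMAL_GLOM: (4, 10),
            CLASS_BLADDER: (2, 12),
            CLASS_BC: (2, 10),
            CLASS_UTI: (1, 5),
        },
        platforms=(("u133plus2", 1.0), ("u133a", 0.8)),
        batch_shift_sd=0.05,
        prior_d0=4.0,
        prior_s0sq=0.05,
        planted_sets={
            "kidney_disease_glom": PlantedSignature(
                n_genes=20,
                target_classes=(CLASS_DKD_GLOM,),
                log2_effect=2.0,
                baseline_offset=-1.5,
            ),
            "bladder_high": PlantedSignature(
                n_genes=30, target_classes=(CLASS_BLADDER,), log2_effect=2.0
            ),
            "leukocyte_high": PlantedSignature(
                n_genes=30, target_classes=(CLASS_UTI,), log2_effect=2.0
            ),
        },
        baseline_mean=8.0,
        seed=seed,
    )


def tubule_contrast_config(
    seed: int = 0,
    n_genes: int = 2000,
    log2_effect: float = math.log2(0.745),
) -> CompendiumConfig:
    """A tubular compendium planting a modest disease-vs-normal shift.

    Defaults plant a 0.745-fold (slightly down-regulated) signature of
    five replicate genes in disease tubules, the regime of a stably
    expressed tubular marker, with a pooled design large enough (40 + 40
    arrays) to estimate the fold change to a few percent.
    """
    return CompendiumConfig(
        n_genes=n_genes,
        tissue_classes=(CLASS_DKD_TUB, CLASS_NORMAL_TUB),
        class_design={CLASS_DKD_TUB: (8, 5), CLASS_NORMAL_TUB: (8, 5)},
        platforms=(("u133plus2", 1.0),),
        batch_shift_sd=0.05,
        prior_d0=4.0,
        prior_s0sq=0.05,
        planted_sets={
            "tubular_marker": PlantedSignature(
                n_genes=5,
                target_classes=(CLASS_DKD_TUB,),
                log2_effect=log2_effect,
            )
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Configuration for a clinical verification cohort.

    Marker relative expression is log-normal within each group with the
    configured linear-scale median and log-scale sigma. Covariates are
    log-normal as well and are coupled to the marker by a Gaussian copula:
    a target Spearman rho maps to the copula correlation r = 2 sin(pi *
    rho / 6), realized through a single-factor construction (covariate
    latent = r * marker latent + sqrt(1 - r^2) * independent noise), which
    is positive semi-definite for any set of valid targets.
    """

    group_sizes: dict[str, int]
    marker_median: dict[str, float]
    marker_sigma: dict[str, float] | float = 1.0
    #: covariate name -> group -> (linear-scale median, log-scale sigma)
    covariates: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    #: covariate name -> target Spearman correlation with the marker
    spearman: dict[str, float] = field(default_factory=dict)
    #: mean Ct of the two housekeeping transcripts used to derive Ct columns
    housekeeping_ct: tuple[float, float] = (19.0, 21.0)
    seed: int = 0


def _marker_sigma(cfg: CohortConfig, group: str) -> float:
    if isinstance(cfg.marker_sigma, dict):
        if group not in cfg.marker_sigma:
            raise ConfigurationError(f"marker_sigma missing group {group!r}")
        return float(cfg.marker_sigma[group])
    return float(cfg.marker_sigma)


def _validate_cohort(cfg: CohortConfig) -> None:
    if not cfg.group_sizes:
        raise ConfigurationError("group_sizes must be non-empty")
    for g, n in cfg.group_sizes.items():
        if n <= 0:
            raise ConfigurationError(f"group_sizes[{g!r}] must be > 0")
        if g not in cfg.marker_median:
            raise ConfigurationError(f"marker_median missing group {g!r}")
        if cfg.marker_median[g] <= 0:
            raise ConfigurationError(f"marker_median[{g!r}] must be > 0")
        if _marker_sigma(cfg, g) < 0:
            raise ConfigurationError(f"marker_sigma[{g!r}] must be >= 0")
    for cov, rho in cfg.spearman.items():
        if not -1.0 <= rho <= 1.0:
            raise ConfigurationError(
                f"spearman[{cov!r}] must be in [-1, 1], got {rho}"
            )
        if cov not in cfg.covariates:
            raise ConfigurationError(f"spearman names unknown covariate {cov!r}")
    for cov, per_group in cfg.covariates.items():
        for g in cfg.group_sizes:
            if g not in per_group:
                raise ConfigurationError(f"covariate {cov!r} missing group {g!r}")
            med, sig = per_group[g]
            if med <= 0 or sig < 0:
                raise ConfigurationError(
                    f"covariate {cov!r}, group {g!r}: median must be > 0, "
                    "sigma >= 0"
                )


def simulate_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Simulate a subject-level cohort table.

    Returns a DataFrame with one row per subject: ``subject_id``, ``group``,
    ``relative_expression`` (linear), derived qPCR columns ``target_ct``,
    ``hk1_ct``, ``hk2_ct`` consistent with the relative expression under
    2^-dCt quantification, and one column per covariate.
    """
    _validate_cohort(cfg)
    streams = np.random.SeedSequence(cfg.seed).spawn(2)
    rng = np.random.default_rng(streams[0])
    rng_ct = np.random.default_rng(streams[1])

    cov_names = list(cfg.covariates)
    copula_r = {
        c: 2.0 * math.sin(math.pi * cfg.spearman.get(c, 0.0) / 6.0)
        for c in cov_names
    }

    rows: list[dict] = []
    sid = 0
    for group, n in cfg.group_sizes.items():
        sigma = _marker_sigma(cfg, group)
        z0 = rng.normal(size=n)
        marker = cfg.marker_median[group] * np.exp(sigma * z0)
        cov_vals: dict[str, np.ndarray] = {}
        for c in cov_names:
            r = copula_r[c]
            z = r * z0 + math.sqrt(max(0.0, 1.0 - r * r)) * rng.normal(size=n)
            med, sig = cfg.covariates[c][group]
            cov_vals[c] = med * np.exp(sig * z)
        hk1 = rng_ct.normal(cfg.housekeeping_ct[0], 0.3, size=n)
        hk2 = rng_ct.normal(cfg.housekeeping_ct[1], 0.3, size=n)
        target_ct = (hk1 + hk2) / 2.0 - np.log2(marker)
        for i in range(n):
            sid += 1
            row = {
                "subject_id": f"S{sid:04d}",
                "group": group,
                "relative_expression": float(marker[i]),
                "target_ct": float(target_ct[i]),
                "hk1_ct": float(hk1[i]),
                "hk2_ct": float(hk2[i]),
            }
            for c in cov_names:
                row[c] = float(cov_vals[c][i])
            rows.append(row)
    return pd.DataFrame(rows)


def stage1_cohort_config(seed: int = 0) -> CohortConfig:
    """Default seven-group verification cohort (82 subjects).

    Group sizes, marker medians and dispersions, and covariate locations
    emulate a first-stage urinary-marker verification study: healthy
    controls at low marker levels, diabetes groups elevated about
    three-fold, end-stage disease back near baseline, and urological
    confounder groups (UTI, bladder cancer) below baseline. Log-scale
    sigmas are derived from interquartile ranges via
    sigma = ln(q75/q25) / 1.349.
    """
    return CohortConfig(
        group_sizes={
            "HC": 14, "NA": 16, "MA": 11, "OA": 12, "ESKD": 13, "UTI": 8, "BC": 8,
        },
        marker_median={
            "HC": 0.0072, "NA": 0.022, "MA": 0.027, "OA": 0.027,
            "ESKD": 0.013, "UTI": 0.005, "BC": 0.006,
        },
        marker_sigma={
            "HC": 1.41, "NA": 1.37, "MA": 1.65, "OA": 1.65,
            "ESKD": 1.26, "UTI": 1.4, "BC": 1.4,
        },
        covariates={
            "acr": {
                "HC": (5.2, 0.80), "NA": (6.4, 0.72), "MA": (120.6, 0.69),
                "OA": (685.9, 1.49), "ESKD": (643.5, 0.36),
                "UTI": (8.0, 0.79), "BC": (10.7, 0.53),
            },
            "nag_cr": {
                "HC": (0.43, 0.33), "NA": (0.60, 0.70), "MA": (1.30, 1.56),
                "OA": (1.90, 1.30), "ESKD": (1.71, 0.61),
                "UTI": (0.51, 0.51), "BC": (1.33, 1.09),
            },
            "glucose": {
                "HC": (5.7, 0.10), "NA": (12.0, 0.51), "MA": (8.9, 0.65),
                "OA": (9.6, 0.51), "ESKD": (5.7, 0.48),
                "UTI": (5.8, 0.15), "BC": (5.7, 0.05),
            },
            "hba1c": {
                "HC": (4.9, 0.10), "NA": (10.1, 0.23), "MA": (8.3, 0.37),
                "OA": (8.6, 0.27), "ESKD": (6.1, 0.31),
                "UTI": (5.3, 0.09), "BC": (4.9, 0.13),
            },
            "egfr": {
                "HC": (101.4, 0.10), "NA": (107.6, 0.30), "MA": (71.1, 0.76),
                "OA": (50.5, 0.72), "ESKD": (11.9, 0.40),
                "UTI": (100.4, 0.21), "BC": (113.8, 0.30),
            },
        },
        spearman={"acr": 0.371, "nag_cr": 0.407, "glucose": 0.323,
                  "hba1c": 0.292, "egfr": 0.0},
        seed=seed,
    )


def stage2_cohort_config(seed: int = 0) -> CohortConfig:
    """Default four-group validation cohort (80 subjects)."""
    return CohortConfig(
        group_sizes={"HC": 20, "NA": 20, "MA": 20, "OA": 20},
        marker_median={"HC": 0.0030, "NA": 0.0064, "MA": 0.0086, "OA": 0.027},
        marker_sigma={"HC": 1.23, "NA": 1.66, "MA": 1.75, "OA": 1.23},
        covariates={
            "acr": {
                "HC": (10.1, 0.86), "NA": (12.0, 0.92),
                "MA": (78.4, 0.69), "OA": (1503.0, 1.33),
            },
            "nag_cr": {
                "HC": (0.48, 0.29), "NA": (0.69, 0.38),
                "MA": (1.17, 0.37), "OA": (1.93, 0.27),
            },
        },
        spearman={"acr": 0.471, "nag_cr": 0.488},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# dilution series
# ---------------------------------------------------------------------------


@dataclass
class DilutionConfig:
    """Configuration for a qPCR dilution-series experiment.

    ``Ct(amount, rep) = intercept - slope * log10(amount) + N(0, noise_sd)``;
    a slope of ~3.32 Ct per log10(ng) corresponds to 100% amplification
    efficiency.
    """

    amounts_ng: tuple[float, ...] = (500.0, 50.0, 5.0, 0.5)
    replicates: int = 3
    #: gene -> (intercept Ct at 1 ng, slope in Ct per log10 ng)
    genes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"BBOX1": (34.0, 3.32), "B2M": (25.0, 3.32)}
    )
    noise_sd: float = 0.1
    seed: int = 0


def simulate_dilution_series(cfg: DilutionConfig) -> pd.DataFrame:
    """Simulate replicate Ct values over a dilution series.

    Returns a tidy DataFrame with columns ``gene``, ``amount_ng``,
    ``replicate``, ``ct``.
    """
    if cfg.replicates < 2:
        raise ConfigurationError("replicates must be >= 2")
    if not cfg.amounts_ng:
        raise ConfigurationError("amounts_ng must be non-empty")
    if any(a <= 0 for a in cfg.amounts_ng):
        raise ConfigurationError("amounts_ng must be strictly positive")
    if len(set(cfg.amounts_ng)) != len(cfg.amounts_ng):
        raise ConfigurationError("amounts_ng must be distinct")
    if cfg.noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if not cfg.genes:
        raise ConfigurationError("genes must be non-empty")

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    rows = []
    for gene, (intercept, slope) in cfg.genes.items():
        for amount in cfg.amounts_ng:
            mu = intercept - slope * math.log10(amount)
            for rep in range(1, cfg.replicates + 1):
                rows.append(
                    {
                        "gene": gene,
                        "amount_ng": float(amount),
                        "replicate": rep,
                        "ct": float(mu + rng.normal(0.0, cfg.noise_sd)),
                    }
                )
    return pd.DataFrame(rows)
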