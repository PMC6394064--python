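"""Tab-separated file formats for matrices, sample sheets, cohorts and
dilution series, plus the planted-truth JSON.

All text is UTF-8 with ``.`` decimals; floats are written with 17
significant digits so write -> read round-trips bit-exactly. Missing
values are empty cells (allowed only before harmonization).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SAMPLE_SHEET_COLUMNS, ExpressionMatrix, PlantedTruth
from .errors import ParseError

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_cohort_tsv",
    "write_cohort_tsv",
    "read_dilution_tsv",
    "write_dilution_tsv",
    "read_truth_json",
    "write_truth_json",
]

_FLOAT_FMT = "%.17g"


def write_expression_tsv(
    m: ExpressionMatrix, values_path: str | Path, samples_path: str | Path
) -> None:
    m.values.to_csv(values_path, sep="\t", float_format=_FLOAT_FMT)
    m.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty file")
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:  # carries the offending line number
        raise ParseError(f"{path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: no parsable content") from exc


def read_expression_tsv(
    values_path: str | Path, samples_path: str | Path
) -> ExpressionMatrix:
    """Read an expression matrix TSV (first column ``gene_id``) plus its
    sample sheet. Duplicate IDs, ragged rows and non-numeric cells raise
    :class:`ParseError` with a line reference."""
    values = _read_tsv(values_path)
    if "gene_id" not in values.columns:
        raise ParseError(f"{values_path}: missing 'gene_id' header column")
    dup = values["gene_id"][values["gene_id"].duplicated()]
    if len(dup):
        line = int(dup.index[0]) + 2  # +1 header, +1 one-based
        raise ParseError(
            f"{values_path}: duplicate gene ID {dup.iloc[0]!r} at line {line}"
        )
    values = values.set_index("gene_id")
    for col in values.columns:
        numeric = pd.to_numeric(values[col], errors="coerce")
        bad = numeric.isna() & values[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(
                f"{values_path}: non-numeric cell in column {col!r} "
                f"at line {line}"
            )
        values[col] = numeric
    samples = _read_tsv(samples_path)
    if "sample_id" not in samples.columns:
        raise ParseError(f"{samples_path}: missing 'sample_id' column")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise ParseError(f"{samples_path}: missing columns {missing}")
    samples = samples.set_index("sample_id")
    return ExpressionMatrix(values=values.astype(float), samples=samples)


def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    # keep_default_na: the normoalbuminuric group is labeled "NA", which
    # pandas would otherwise silently turn into missing values
    cohort = _read_tsv(path, keep_default_na=False, na_values=[""])
    for required in ("subject_id", "group"):
        if required not in cohort.columns:
            raise ParseError(f"{path}: missing column {required!r}")
    return cohort


def write_dilution_tsv(dilution: pd.DataFrame, path: str | Path) -> None:
    dilution.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_dilution_tsv(path: str | Path) -> pd.DataFrame:
    dilution = _read_tsv(path)
    missing = {"gene", "amount_ng", "replicate", "ct"} - set(dilution.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return dilution


def write_truth_json(truth: PlantedTruth, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_truth_json(path: str | Path) -> PlantedTruth:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return PlantedTruth.from_dict(payload)
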