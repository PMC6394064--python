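"""Bundled reference measurements used by the worked examples.

Small plain-number tables from a published two-stage urinary-marker
verification study, shipped so the clinical statistics can be exercised on
real printed values: a Taqman qPCR dilution-series reproducibility
experiment (triplicate Ct values of the BBOX1 target and the B2M
housekeeping transcript at four input-RNA amounts), and the stage-1
marker summary (group medians and raw rank-test p-values for four urinary
mRNAs).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "taqman_dilution_cts",
    "STAGE1_MARKER_MEDIANS",
    "STAGE1_MARKER_RAW_P",
]

_TAQMAN_CTS = {
    ("BBOX1", 500.0): (25.29, 25.54, 25.38),
    ("B2M", 500.0): (15.51, 15.58, 15.52),
    ("BBOX1", 50.0): (28.19, 28.26, 28.24),
    ("B2M", 50.0): (18.84, 18.81, 18.85),
    ("BBOX1", 5.0): (31.55, 31.43, 31.42),
    ("B2M", 5.0): (22.25, 22.29, 22.20),
    ("BBOX1", 0.5): (33.87, 33.86, 34.06),
    ("B2M", 0.5): (25.74, 25.73, 25.71),
}

#: Printed per-dilution CV percentages of the same experiment, by gene,
#: in descending amount order (500, 50, 5, 0.5 ng).
TAQMAN_PRINTED_CV = {
    "BBOX1": (0.49, 0.10, 0.19, 0.27),
    "B2M": (0.24, 0.09, 0.17, 0.05),
}


def taqman_dilution_cts() -> pd.DataFrame:
    """The dilution-series Ct triplicates as a tidy DataFrame
    (columns gene, amount_ng, replicate, ct)."""
    rows = [
        {"gene": gene, "amount_ng": amount, "replicate": i + 1, "ct": ct}
        for (gene, amount), cts in _TAQMAN_CTS.items()
        for i, ct in enumerate(cts)
    ]
    return pd.DataFrame(rows)


#: Stage-1 urinary marker relative-expression medians: marker ->
#: (control group median, disease group median).
STAGE1_MARKER_MEDIANS = {
    "BBOX1": (0.0072, 0.027),
    "CCL18": (0.0017, 0.016),
    "NPHS2": (0.039, 0.085),
    "SLC3A1": (0.0023, 0.014),
}

#: Raw disease-vs-control rank-test p-values for the same four markers.
STAGE1_MARKER_RAW_P = {
    "BBOX1": 0.0021,
    "CCL18": 0.0094,
    "NPHS2": 0.024,
    "SLC3A1": 0.031,
}
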