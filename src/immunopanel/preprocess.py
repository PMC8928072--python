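"""Per-sample normalization and transforms applied before scoring.

All downstream scores are rank-based within a sample (ssGSEA) or within a
gene (sum of ranks), so these strictly monotone transforms never change the
scores; they exist to reproduce the study's preprocessing chain and to make
expression values comparable for threshold-based subtype grouping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import ExpressionMatrix

#: breast-cancer-like subtype labels (advisory grouping keys only)
SUBTYPE_HR = "HR+/HER2--like"
SUBTYPE_HER2 = "HER2+-like"
SUBTYPE_TN = "TN-like"


@dataclass(frozen=True)
class TransformParams:
    """Parameters of the expression transforms.

    log_shift_scale
        The constant ``a`` in ``x -> log2(1 + a*x)``; default 1023 so that
        x = 1 maps to exactly 10.
    esr1_threshold, erbb2_threshold
        Cutoffs on *log-transformed* ESR1/ERBB2 expression for subtype
        grouping.  No defaults are shipped: they depend on the cohort's
        expression unit and must be supplied by the user (a two-component
        fit's antimode is a reasonable procedure).
    """

    log_shift_scale: float = 1023.0
    esr1_threshold: float | None = None
    erbb2_threshold: float | None = None

    def __post_init__(self) -> None:
        if not self.log_shift_scale > 0:
            raise ValidationError("log_shift_scale must be > 0")


def median_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample's values by that sample's median across all genes.

    The median is taken over every gene in the (post-intersection) universe,
    zeros included.  Post-condition: every sample's median equals 1.
    """
    medians = matrix.data.median(axis=0)
    zero = medians[medians <= 0]
    if len(zero):
        raise ValidationError(
            f"per-sample median is zero for sample(s): {zero.index.tolist()}"
        )
    return ExpressionMatrix(matrix.data / medians)


def log_transform(
    matrix: ExpressionMatrix, params: TransformParams | None = None
) -> ExpressionMatrix:
    """Elementwise ``x -> log2(1 + a*x)`` with a = ``log_shift_scale``.

    Maps 0 to exactly 0 and (with the default a = 1023) 1 to exactly 10;
    strictly increasing, so rank-based scores are invariant to it.
    """
    params = params or TransformParams()
    values = matrix.data.to_numpy()
    if (values < 0).any():
        raise ValidationError("log_transform requires non-negative input")
    out = np.log2(1.0 + params.log_shift_scale * values)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    )


def classify_breast_subtypes(
    matrix: ExpressionMatrix, params: TransformParams
) -> pd.Series:
    """Group samples into three clinical-subtype-like labels from ESR1/ERBB2.

    Thresholds apply to log-transformed expression: ERBB2 >= t2 is
    HER2+-like regardless of ESR1; otherwise ESR1 >= t1 is HR+/HER2--like;
    otherwise TN-like.  Labels are advisory grouping keys for stratified
    analysis, not clinical calls.
    """
    for gene in ("ESR1", "ERBB2"):
        if gene not in matrix.data.index:
            raise ValidationError(f"gene {gene!r} missing from matrix")
    if params.esr1_threshold is None or params.erbb2_threshold is None:
        raise ValidationError(
            "subtype thresholds are required: supply esr1_threshold and "
            "erbb2_threshold (cutoffs on log-transformed expression); "
            "no defaults are shipped"
        )
    logm = log_transform(matrix, params)
    esr1 = logm.data.loc["ESR1"]
    erbb2 = logm.data.loc["ERBB2"]
    labels = np.where(
        erbb2 >= params.erbb2_threshold,
        SUBTYPE_HER2,
        np.where(esr1 >= params.esr1_threshold, SUBTYPE_HR, SUBTYPE_TN),
    )
    return pd.Series(labels, index=logm.data.columns, name="subtype")
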