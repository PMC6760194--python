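"""Count -> FPKM -> log2 conversion.

FPKM(g, s) = count(g, s) * 1e9 / (length_bp(g) * total(s)), with the
per-sample total defaulting to the column sum of the count matrix (a
per-sample totals override is accepted).  Expression is then
log2-transformed with a pseudocount so that zeros stay finite; downstream
statistics are computed on the log2 scale, where bulk expression is
approximately normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance with a processing-stage tag.

    ``stage`` is one of ``counts | fpkm | log2fpkm``; ``pseudocount``
    records the offset used when ``stage == "log2fpkm"``.
    """

    values: pd.DataFrame
    roles: pd.Series
    stage: str
    pseudocount: float | None = None

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.roles.index[self.roles == "tumor"])

    @property
    def reference_samples(self) -> list[str]:
        return list(self.roles.index[self.roles == "reference"])


def compute_fpkm(
    counts: CountMatrix,
    annotation: pd.DataFrame,
    totals: pd.Series | None = None,
) -> ExpressionMatrix:
    """Convert raw counts to FPKM.

    Every gene must carry a transcript length in ``annotation``.  A sample
    whose total is zero yields an all-zero column with a warning.
    """
    if counts.counts.empty:
        raise ValidationError("empty count matrix")
    missing = counts.counts.index.difference(annotation.index)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} genes lack annotation (no length_bp); "
            "use align_genes() first"
        )
    lengths = annotation.loc[counts.counts.index, "length_bp"].astype(float)
    if totals is None:
        totals = counts.counts.sum(axis=0).astype(float)
    else:
        totals = totals.reindex(counts.counts.columns).astype(float)
        if totals.isna().any():
            raise ValidationError("totals missing for some samples")
    zero = totals == 0
    if zero.any():
        logger.warning("%d samples have zero total counts", int(zero.sum()))
        totals = totals.replace(0, np.nan)
    fpkm = counts.counts.astype(float).mul(1e9).div(lengths, axis=0).div(totals, axis=1)
    fpkm = fpkm.fillna(0.0)
    return ExpressionMatrix(fpkm, counts.roles, stage="fpkm")


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(FPKM + pseudocount); monotone in FPKM.

    With ``pseudocount == 0`` any zero FPKM would map to -inf, so that case
    is rejected with advice to supply a pseudocount.
    """
    if expr.stage != "fpkm":
        raise ValidationError(f"log2_transform expects stage 'fpkm', got {expr.stage!r}")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if pseudocount == 0 and (expr.values.to_numpy() == 0).any():
        raise ValidationError(
            "zero FPKM present with pseudocount=0; supply a positive pseudocount"
        )
    values = np.log2(expr.values + pseudocount)
    return ExpressionMatrix(values, expr.roles, stage="log2fpkm", pseudocount=pseudocount)
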