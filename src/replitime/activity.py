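"""Transcriptional activity classes (0-4) and the ON/OFF dichotomy.

Non-transcribed promoters (expression at or below ``zero_threshold``,
default exactly 0) form class 0; transcribed promoters are split by the
expression quartiles of the transcribed subset into classes 1-4 (lowest
quartile = 1).  Classes 0 and 1 are inactive (OFF); classes 2-4 are active
(ON).  Class assignment is rank-based — class = ceil(4 * rank / n) — so it
is invariant under any strictly monotone transform of expression; tied
values share the minimum rank of their tie group, so a tie spanning a
quartile boundary takes the lower class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["classify_activity", "split_on_off"]


def classify_activity(
    expression: pd.DataFrame, zero_threshold: float = 0.0
) -> pd.DataFrame:
    """Assign activity classes 0-4 and ON/OFF status per promoter.

    ``expression`` has columns (promoter_id, expression); a gene_id column
    is accepted as an alias.  Negative or non-finite expression raises.
    """
    expr = expression.copy()
    if "promoter_id" not in expr.columns and "gene_id" in expr.columns:
        expr = expr.rename(columns={"gene_id": "promoter_id"})
    values = expr["expression"].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression values must be finite")
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")

    classes = np.zeros(len(values), dtype=np.int64)
    transcribed = values > zero_threshold
    n = int(transcribed.sum())
    if n:
        ranks = rankdata(values[transcribed], method="min")
        classes[transcribed] = -(-4 * ranks // n)  # ceil(4 r / n)
    status = np.where(classes >= 2, "ON", "OFF")
    return pd.DataFrame(
        {
            "promoter_id": expr["promoter_id"].to_numpy(),
            "expression": values,
            "activity_class": classes,
            "status": status,
        }
    )


def split_on_off(classes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition an activity table into (ON, OFF); disjoint and exhaustive."""
    on = classes[classes["status"] == "ON"].reset_index(drop=True)
    off = classes[classes["status"] == "OFF"].reset_index(drop=True)
    return on, off
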