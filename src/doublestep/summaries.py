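"""Descriptive aggregation of per-trial measures.

Cell summaries follow two-stage aggregation: trials are averaged within
participant first, and cell means are means of participant means, so
participants with unequal retained-trial counts contribute equally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["percent_difference", "condition_summary", "participant_means"]


def percent_difference(a: float, b: float) -> int:
    """|a - b| divided by the mean of a and b, times 100, to the nearest integer."""
    denom = (a + b) / 2.0
    if denom == 0:
        raise ValueError("percent_difference undefined when a + b = 0")
    return int(round(abs(a - b) / denom * 100.0))


_CELL = ["group", "condition_ms", "direction"]


def participant_means(trial_table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Per-participant mean of each dependent variable within each cell."""
    return (
        trial_table
        .groupby(["participant"] + _CELL, dropna=False, observed=True)[variables]
        .mean()
        .reset_index()
        .sort_values(["participant"] + _CELL, na_position="first")
        .reset_index(drop=True)
    )


def condition_summary(trial_table: pd.DataFrame, variables: list[str],
                      two_stage: bool = True) -> pd.DataFrame:
    """Cell-level summary table (mean, SD, n, min, max per dependent variable).

    ``n`` is the retained trial count in the cell; with ``two_stage`` the
    mean and SD are computed over participant means (the default), else
    over pooled trials.  Rows are deterministically ordered; empty cells
    simply do not appear (missing, not zero).
    """
    counts = (trial_table.groupby(_CELL, dropna=False, observed=True)
              .size().rename("n_trials"))
    source = participant_means(trial_table, variables) if two_stage else trial_table
    agg = (
        source
        .groupby(_CELL, dropna=False, observed=True)[variables]
        .agg(["mean", "std", "count", "min", "max"])
    )
    agg.columns = [f"{var}_{stat}" for var, stat in agg.columns]
    out = agg.join(counts).reset_index()
    return (out.sort_values(_CELL, na_position="first", kind="mergesort")
            .reset_index(drop=True))
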