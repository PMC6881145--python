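"""Group statistics recomputed from published per-figure source tables.

Input is the tidy long format produced by :func:`ieplast.io.load_source_data`:
columns (cell_id, condition, timepoint, metric, value) with timepoints
'pre' and a post label.  For each condition and metric the per-cell
percent change, group mean +/- SEM, the within-group paired t-test and
(against a reference condition) the between-group two-tailed t-test are
reported — the same statistics used for the simulated cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import percent_change


def source_percent_changes(
    table: pd.DataFrame, pre_label: str = "pre", post_label: str = "20"
) -> pd.DataFrame:
    """Per-cell percent change per condition and metric."""
    wide = table.pivot_table(
        index=["cell_id", "condition", "metric"], columns="timepoint", values="value"
    ).reset_index()
    if pre_label not in wide.columns or post_label not in wide.columns:
        raise ValueError(
            f"timepoints {pre_label!r} and {post_label!r} required; got {list(wide.columns)}"
        )
    wide["change_pct"] = [
        percent_change(a, b) for a, b in zip(wide[pre_label], wide[post_label])
    ]
    wide = wide.rename(columns={pre_label: "pre_value", post_label: "post_value"})
    return wide[["cell_id", "condition", "metric", "pre_value", "post_value", "change_pct"]]


def source_data_stats(
    table: pd.DataFrame,
    reference_condition: str | None = None,
    pre_label: str = "pre",
    post_label: str = "20",
) -> pd.DataFrame:
    """Group mean +/- SEM of percent changes with paired and between-group
    t-tests, one row per condition x metric."""
    changes = source_percent_changes(table, pre_label, post_label)
    conditions = list(changes["condition"].unique())
    if reference_condition is None:
        reference_condition = conditions[0]
    rows = []
    for (cond, metric), grp in changes.groupby(["condition", "metric"]):
        grp = grp.dropna(subset=["change_pct"])
        if len(grp) < 2:
            continue
        paired = sps.ttest_rel(grp["pre_value"], grp["post_value"]).pvalue
        row = {
            "condition": cond,
            "metric": metric,
            "n": len(grp),
            "mean_change_pct": float(grp["change_pct"].mean()),
            "sem_change_pct": float(grp["change_pct"].sem()),
            "paired_p": float(paired),
        }
        if cond != reference_condition:
            ref = changes[
                (changes["condition"] == reference_condition)
                & (changes["metric"] == metric)
            ].dropna(subset=["change_pct"])
            if len(ref) >= 2:
                row["between_p_vs_reference"] = float(
                    sps.ttest_ind(grp["change_pct"], ref["change_pct"]).pvalue
                )
        rows.append(row)
    return pd.DataFrame(rows)
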