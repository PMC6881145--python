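"""Group-level plasticity statistics.

Within-group comparisons are paired t-tests on pre vs post values;
between-group comparisons are two-tailed two-sample t-tests on per-cell
percent changes.  Relationships with induction strength use ordinary
least squares on (evoked spike count, percent change) pairs.  Results
are reported as mean +/- SEM with the group n, mirroring standard
electrophysiology reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CellSession
from .features import extract_features
from .iocurve import IOCurve, NormalizedIO, build_io_curve, normalize_io

#: feature columns carried through the cohort feature table
FEATURE_COLUMNS = (
    "rin",
    "sag_ratio",
    "ap_threshold",
    "ahp_min",
    "latency_ms",
    "burst_index",
    "vm_variance",
    "max_step_count",
    "rs",
    "vm_rest",
    "spike_amplitude",
)

#: metrics reported as percent changes in the group comparisons
CHANGE_METRICS = ("max_step_count", "rin", "latency_ms", "sag_ratio")


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values.  Not applied by default (single
    comparisons are reported unadjusted, as is conventional for these
    designs); callers opt in for families of tests."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def percent_change(pre_value: float, post_value: float) -> float:
    """100 * (post - pre) / pre; undefined (NaN) when pre is 0 or missing."""
    if pre_value is None or post_value is None or pre_value == 0:
        return float("nan")
    return 100.0 * (post_value - pre_value) / pre_value


def dtx_subset_filter(cells: pd.DataFrame, min_spikes: int = 250) -> pd.DataFrame:
    """Keep cells whose induction evoked at least ``min_spikes`` spikes
    (inclusive), the criterion used when comparing Kv1.1-block cohorts."""
    return cells[cells["tbs_spike_count"] >= min_spikes]


def cohort_features(
    cells: Iterable[CellSession], timepoints: Sequence[str] | None = None
) -> pd.DataFrame:
    """Extract the full feature table for a cohort.

    One row per cell x timepoint; accepts an iterator of cells so large
    cohorts can be processed without holding all sweeps in memory.
    """
    rows = []
    for cell in cells:
        tps = timepoints or list(cell.blocks)
        for tp in tps:
            feats = extract_features(cell.blocks[tp], cell.spont.get(tp))
            row = {
                "cell_id": cell.cell_id,
                "condition": cell.condition,
                "timepoint": tp,
                "tbs_spike_count": cell.tbs_spike_count,
            }
            for name in FEATURE_COLUMNS:
                row[name] = getattr(feats, name)
            row["spike_counts"] = feats.spike_counts
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_changes(
    features: pd.DataFrame, post_timepoint: str = "20", metrics: Sequence[str] = CHANGE_METRICS
) -> pd.DataFrame:
    """Per-cell percent changes between pre and a post timepoint."""
    pre = features[features["timepoint"] == "pre"].set_index("cell_id")
    post = features[features["timepoint"] == post_timepoint].set_index("cell_id")
    rows = []
    for cid in pre.index:
        if cid not in post.index:
            continue
        row = {
            "cell_id": cid,
            "condition": pre.loc[cid, "condition"],
            "tbs_spike_count": pre.loc[cid, "tbs_spike_count"],
        }
        for m in metrics:
            row[f"change_{m}"] = percent_change(pre.loc[cid, m], post.loc[cid, m])
            row[f"pre_{m}"] = pre.loc[cid, m]
            row[f"post_{m}"] = post.loc[cid, m]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Between-group comparison of one percent-change metric."""

    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    paired_p_a: float      # pre vs post within group a
    paired_p_b: float
    between_p: float       # two-sample two-tailed t on percent changes


def group_stats(
    changes: pd.DataFrame,
    group_a: str,
    group_b: str,
    metric: str = "max_step_count",
) -> GroupComparison:
    """Paired t within each group (pre vs post raw values), two-sample
    two-tailed t between groups on the percent changes."""
    a = changes[changes["condition"] == group_a].dropna(subset=[f"change_{metric}"])
    b = changes[changes["condition"] == group_b].dropna(subset=[f"change_{metric}"])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    pa = sps.ttest_rel(a[f"pre_{metric}"], a[f"post_{metric}"]).pvalue
    pb = sps.ttest_rel(b[f"pre_{metric}"], b[f"post_{metric}"]).pvalue
    pt = sps.ttest_ind(a[f"change_{metric}"], b[f"change_{metric}"]).pvalue
    ca, cb = a[f"change_{metric}"], b[f"change_{metric}"]
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(ca.mean()),
        sem_a=float(ca.sem()),
        mean_b=float(cb.mean()),
        sem_b=float(cb.sem()),
        paired_p_a=float(pa),
        paired_p_b=float(pb),
        between_p=float(pt),
    )


def correlate_with_stimulation(
    tbs_spike_counts: Sequence[float], changes: Sequence[float]
) -> dict[str, float]:
    """OLS of percent change on evoked spike count: R^2 and slope p."""
    x = np.asarray(tbs_spike_counts, dtype=float)
    y = np.asarray(changes, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need n >= 3 pairs")
    if np.var(x) == 0:
        raise ValueError("zero variance in spike counts")
    res = sps.linregress(x, y)
    return {
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "n": int(len(x)),
    }


def normalized_population(
    features: pd.DataFrame, timepoints: Sequence[str] = ("pre", "10", "20", "30")
) -> list[NormalizedIO]:
    """Build per-cell normalized I/O curves for every timepoint, using
    each cell's pre curve as the normalization reference."""
    out: list[NormalizedIO] = []
    for cid, grp in features.groupby("cell_id"):
        grp = grp.set_index("timepoint")
        if "pre" not in grp.index:
            continue
        pre_counts = grp.loc["pre", "spike_counts"]
        pre_curve = build_io_curve(
            {a: [c] for a, c in pre_counts.items()}, cid, "pre"
        )
        if pre_curve.mean_counts[-1] == pre_curve.mean_counts[0]:
            continue
        for tp in timepoints:
            if tp not in grp.index:
                continue
            counts = grp.loc[tp, "spike_counts"]
            curve = build_io_curve({a: [c] for a, c in counts.items()}, cid, tp)
            out.append(normalize_io(curve, pre_curve))
    return out
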