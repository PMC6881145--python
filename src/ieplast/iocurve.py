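"""Input-output (current vs spike count) curves and their comparison.

Curves are normalized per cell with the pre-induction block as the
reference: spike counts map through ``(X - minPre) / (maxPre - minPre)``
where minPre/maxPre are the pre-block mean counts at the smallest and
largest step, and the current axis maps linearly onto [0, 1] over the
cell's step range.  Population curves at two timepoints are compared by
pooled linear regression with a full timepoint interaction, which tests
the intercept (rightward shift) and the slope (gain) separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf


@dataclass(frozen=True)
class IOCurve:
    """Mean spike count per step amplitude for one cell at one timepoint."""

    cell_id: str
    timepoint: str
    amplitudes: tuple[float, ...]
    mean_counts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.amplitudes) != len(self.mean_counts):
            raise ValueError("amplitudes and counts must align")
        if np.any(np.diff(self.amplitudes) <= 0):
            raise ValueError("amplitudes must be strictly increasing")
        if np.any(np.asarray(self.mean_counts) < 0):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class NormalizedIO:
    """Normalized curve: current in [0, 1], counts in pre-referenced units."""

    cell_id: str
    timepoint: str
    norm_current: tuple[float, ...]
    norm_count: tuple[float, ...]


class DegenerateCurveError(ValueError):
    pass


def build_io_curve(
    spike_counts: Mapping[float, Sequence[float]], cell_id: str, timepoint: str
) -> IOCurve:
    """Average spike counts over repeats per amplitude (zeros retained)."""
    if len(spike_counts) < 3:
        raise ValueError("need >= 3 depolarizing amplitudes")
    amps = sorted(spike_counts)
    means = [float(np.mean(spike_counts[a])) for a in amps]
    return IOCurve(cell_id=cell_id, timepoint=timepoint, amplitudes=tuple(amps), mean_counts=tuple(means))


def normalize_io(curve: IOCurve, pre: IOCurve) -> NormalizedIO:
    """Normalize ``curve`` against the cell's pre-induction curve.

    Counts: ``(X - minPre) / (maxPre - minPre)`` with minPre/maxPre the
    pre-curve means at its smallest/largest amplitude.  Current: linear
    map of the cell's [min_amp, max_amp] onto [0, 1].
    """
    min_pre = pre.mean_counts[0]
    max_pre = pre.mean_counts[-1]
    if max_pre == min_pre:
        raise DegenerateCurveError("pre curve has equal min and max mean counts")
    a0, a1 = curve.amplitudes[0], curve.amplitudes[-1]
    if a1 == a0:
        raise DegenerateCurveError("degenerate amplitude range")
    cur = tuple((a - a0) / (a1 - a0) for a in curve.amplitudes)
    cnt = tuple((x - min_pre) / (max_pre - min_pre) for x in curve.mean_counts)
    return NormalizedIO(
        cell_id=curve.cell_id, timepoint=curve.timepoint, norm_current=cur, norm_count=cnt
    )


def compare_io_fits(
    population: Sequence[NormalizedIO],
    timepoint_a: str,
    timepoint_b: str,
    cluster_by_cell: bool = True,
) -> dict[str, float]:
    """Test for slope and intercept differences between two timepoints.

    All cells' normalized points are pooled per timepoint and fitted with
    a single regression including a timepoint factor and its interaction
    with current; the factor p-value tests the intercept difference, the
    interaction p-value the slope (gain) difference.

    Each cell contributes several points whose deviations from the
    population line are correlated (a cell's whole curve sits high or
    low together), so by default the coefficient covariance is
    cluster-robust with the cell as the cluster; treating the points as
    independent (``cluster_by_cell=False``) makes both tests
    anti-conservative.
    """
    rows = []
    for nio in population:
        if nio.timepoint not in (timepoint_a, timepoint_b):
            continue
        for c, y in zip(nio.norm_current, nio.norm_count):
            rows.append({"current": c, "count": y, "tp": nio.timepoint, "cell": nio.cell_id})
    df = pd.DataFrame(rows)
    n_a = (df["tp"] == timepoint_a).sum()
    n_b = (df["tp"] == timepoint_b).sum()
    if n_a == 0 or n_b == 0:
        raise ValueError("both timepoints must be present in the population")
    df["tp"] = pd.Categorical(df["tp"], categories=[timepoint_a, timepoint_b])
    ols = smf.ols("count ~ current * tp", data=df)
    if cluster_by_cell and df["cell"].nunique() > 1:
        model = ols.fit(cov_type="cluster", cov_kwds={"groups": df["cell"]})
    else:
        model = ols.fit()
    name_int = f"tp[T.{timepoint_b}]"
    name_slope = f"current:tp[T.{timepoint_b}]"
    return {
        "intercept_p": float(model.pvalues[name_int]),
        "slope_p": float(model.pvalues[name_slope]),
        "intercept_diff": float(model.params[name_int]),
        "slope_diff": float(model.params[name_slope]),
        "n_points": int(len(df)),
    }
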