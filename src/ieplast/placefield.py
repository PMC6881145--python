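"""Place-field analysis: rate maps, in/out-of-field firing by lap,
session thirds, lap-by-lap correlations and population tests.

The analysis chain mirrors how linear-track place-cell sessions are
screened and quantified: laps are segmented at trajectory turnarounds
and each running direction analyzed independently; per-lap spatial rate
maps (spikes over occupancy per bin) give a session-mean map; the place
field is the contiguous region around the peak above 20% of the peak
rate; cells are included when both stability (mean pairwise lap-map
correlation) and spatial information (bits/spike) exceed 0.1; firing
drift is measured by session thirds and the Pearson correlation of
per-lap rate against lap number; population-level drift is tested with
a repeated-measures ANOVA across thirds and a center test (one-tailed t
or sign test by normality) on the per-cell correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .placesim import PlaceSession

FIELD_FRACTION = 0.2
INCLUSION_THRESHOLD = 0.1
DEFAULT_BIN_CM = 2.0


@dataclass
class RateMap:
    bin_edges: np.ndarray            # cm, len n_bins + 1
    lap_counts: np.ndarray           # (n_laps, n_bins) spikes
    lap_occupancy: np.ndarray        # (n_laps, n_bins) s
    lap_rate: np.ndarray             # Hz, NaN where occupancy is 0
    mean_rate: np.ndarray            # Hz, total spikes / total occupancy
    occupancy: np.ndarray            # s per bin (total)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


@dataclass
class SessionStats:
    in_rate_per_lap: np.ndarray      # Hz
    out_rate_per_lap: np.ndarray     # Hz
    lap_times: np.ndarray            # s, lap midpoints
    thirds_out: tuple[float, float, float]
    thirds_in: tuple[float, float, float]
    lap_corr_in: float
    lap_corr_out: float
    stability: float
    spatial_info: float
    field: tuple[int, int] | None    # bin interval [lo, hi)


def segment_laps(
    t: np.ndarray, x: np.ndarray, track_length: float, min_span_frac: float = 0.5
) -> dict[int, list[tuple[float, float]]]:
    """Split a back-and-forth trajectory into laps per running direction.

    Turnarounds are sign changes of the position increment; runs whose
    spatial span is below ``min_span_frac`` of the track are discarded as
    jitter.  Returns {direction (+1/-1): [(t_start, t_end), ...]}.
    """
    dx = np.diff(x)
    direction = np.sign(dx)
    direction[direction == 0] = 0
    # boundaries where the (nonzero) direction changes
    nz = np.flatnonzero(direction)
    if len(nz) == 0:
        raise ValueError("stationary trajectory: no laps")
    changes = [0]
    cur = direction[nz[0]]
    for k in nz:
        if direction[k] != cur:
            changes.append(k)
            cur = direction[k]
    changes.append(len(x) - 1)
    if len(changes) < 3:
        # fewer than 2 turnarounds and the trace is one monotone run:
        # accept the single run only if it spans the track
        if abs(x[-1] - x[0]) < min_span_frac * track_length:
            raise ValueError("fewer than 2 turnarounds in trajectory")
    laps: dict[int, list[tuple[float, float]]] = {1: [], -1: []}
    for a, b in zip(changes[:-1], changes[1:]):
        if abs(x[b] - x[a]) < min_span_frac * track_length:
            continue
        d = 1 if x[b] > x[a] else -1
        laps[d].append((float(t[a]), float(t[b])))
    if not laps[1] and not laps[-1]:
        raise ValueError("no laps spanning the track")
    return laps


def compute_rate_map(
    session: PlaceSession, bin_cm: float = DEFAULT_BIN_CM
) -> RateMap:
    """Per-lap and session-mean spatial rate maps (spikes / occupancy)."""
    if bin_cm <= 0:
        raise ValueError("bin_cm must be positive")
    edges = np.arange(0.0, session.track_length + bin_cm, bin_cm)
    if edges[-1] < session.track_length:
        edges = np.append(edges, session.track_length)
    n_bins = len(edges) - 1
    n_laps = session.n_laps
    dt = float(np.median(np.diff(session.t[: max(2, min(100, len(session.t)))])))
    counts = np.zeros((n_laps, n_bins))
    occ = np.zeros((n_laps, n_bins))
    t_arr, x_arr, sp = session.t, session.x, session.spike_times
    for li, (t0, t1, _d) in enumerate(session.laps):
        a, b = np.searchsorted(t_arr, (t0, t1))
        occ[li], _ = np.histogram(x_arr[a:b], bins=edges)
        occ[li] *= dt
        sa, sb = np.searchsorted(sp, (t0, t1))
        lo, hi = max(a - 1, 0), min(b + 1, len(t_arr))
        xs = np.interp(sp[sa:sb], t_arr[lo:hi], x_arr[lo:hi])
        counts[li], _ = np.histogram(xs, bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        lap_rate = counts / occ
    tot_occ = occ.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_rate = counts.sum(axis=0) / tot_occ
    return RateMap(
        bin_edges=edges,
        lap_counts=counts,
        lap_occupancy=occ,
        lap_rate=lap_rate,
        mean_rate=mean_rate,
        occupancy=tot_occ,
    )


def detect_field(
    mean_rate: np.ndarray, fraction: float = FIELD_FRACTION
) -> tuple[int, int] | None:
    """Largest contiguous run of bins >= ``fraction`` of the peak rate
    that contains the peak bin; ``None`` for an all-zero map.  Ties on
    the peak go to the first position."""
    rate = np.nan_to_num(np.asarray(mean_rate, dtype=float))
    peak = rate.max()
    if peak <= 0:
        return None
    pk = int(np.argmax(rate))
    thresh = fraction * peak
    lo = pk
    while lo > 0 and rate[lo - 1] >= thresh:
        lo -= 1
    hi = pk + 1
    while hi < len(rate) and rate[hi] >= thresh:
        hi += 1
    return (lo, hi)


def infield_outfield_rates(
    session: PlaceSession, rmap: RateMap, fld: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-lap firing rates inside and outside the field (spikes over
    time spent in the respective bins).  Laps with zero out-of-field
    occupancy yield NaN for that lap."""
    lo, hi = fld
    in_mask = np.zeros(rmap.n_bins, dtype=bool)
    in_mask[lo:hi] = True
    in_spk = rmap.lap_counts[:, in_mask].sum(axis=1)
    out_spk = rmap.lap_counts[:, ~in_mask].sum(axis=1)
    in_occ = rmap.lap_occupancy[:, in_mask].sum(axis=1)
    out_occ = rmap.lap_occupancy[:, ~in_mask].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return in_spk / in_occ, out_spk / out_occ


def stability(lap_rate: np.ndarray) -> float:
    """Mean of all pairwise Pearson correlations between per-lap rate
    vectors; laps (or pairs) with zero variance or undefined bins are
    skipped, with the pair count reduced accordingly."""
    n_laps = lap_rate.shape[0]
    if n_laps < 2:
        raise ValueError("stability needs >= 2 laps")
    if np.all(np.isfinite(lap_rate)):
        # fast path: one correlation matrix over laps with variance
        valid = np.flatnonzero(np.std(lap_rate, axis=1) > 0)
        if len(valid) < 2:
            return float("nan")
        c = np.corrcoef(lap_rate[valid])
        iu = np.triu_indices(len(valid), k=1)
        return float(np.mean(c[iu]))
    vals = []
    for i in range(n_laps):
        for j in range(i + 1, n_laps):
            a, b = lap_rate[i], lap_rate[j]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
                continue
            vals.append(float(np.corrcoef(a[ok], b[ok])[0, 1]))
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def spatial_information(mean_rate: np.ndarray, occupancy: np.ndarray) -> float | None:
    """Skaggs spatial information in bits per spike:
    sum_i p_i (r_i / r) log2(r_i / r), p_i = occupancy fraction."""
    occ = np.asarray(occupancy, dtype=float)
    rate = np.nan_to_num(np.asarray(mean_rate, dtype=float))
    ok = occ > 0
    p = occ[ok] / occ[ok].sum()
    r = rate[ok]
    rbar = float(np.sum(p * r))
    if rbar <= 0:
        return None
    ratio = r / rbar
    terms = np.where(ratio > 0, p * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    return float(terms.sum())


def include_cell(stab: float, spatial_info: float, threshold: float = INCLUSION_THRESHOLD) -> bool:
    """Stability and spatial information must both exceed the threshold
    (strictly)."""
    if not np.isfinite(stab) or spatial_info is None:
        return False
    return stab > threshold and spatial_info > threshold


def session_thirds(
    per_lap_rates: np.ndarray, lap_mid_times: np.ndarray, session_span: tuple[float, float]
) -> tuple[float, float, float]:
    """Mean per-lap rate in the start/middle/end thirds of the session
    (split by duration; laps assigned by midpoint time, boundary laps to
    the earlier third).  Empty thirds yield NaN."""
    t0, t1 = session_span
    length = t1 - t0
    b1, b2 = t0 + length / 3.0, t0 + 2.0 * length / 3.0
    rates = np.asarray(per_lap_rates, dtype=float)
    mids = np.asarray(lap_mid_times, dtype=float)
    thirds = []
    masks = [mids <= b1, (mids > b1) & (mids <= b2), mids > b2]
    for m in masks:
        vals = rates[m & np.isfinite(rates)]
        thirds.append(float(np.mean(vals)) if len(vals) else float("nan"))
    return tuple(thirds)  # type: ignore[return-value]


def lap_rate_correlation(per_lap_rates: np.ndarray) -> float:
    """Pearson correlation between lap number and per-lap rate; NaN when
    fewer than 3 finite laps or the rates have zero variance."""
    rates = np.asarray(per_lap_rates, dtype=float)
    idx = np.arange(len(rates), dtype=float)
    ok = np.isfinite(rates)
    if ok.sum() < 3 or np.std(rates[ok]) == 0:
        return float("nan")
    return float(np.corrcoef(idx[ok], rates[ok])[0, 1])


def session_stats(session: PlaceSession, bin_cm: float = DEFAULT_BIN_CM) -> SessionStats:
    """Full per-cell screening and drift statistics for one session."""
    rmap = compute_rate_map(session, bin_cm)
    fld = detect_field(rmap.mean_rate)
    mids = np.array([(a + b) / 2.0 for a, b, _ in session.laps])
    span = (float(session.t[0]), float(session.t[-1]))
    if fld is None:
        nan3 = (float("nan"),) * 3
        empty = np.full(session.n_laps, np.nan)
        return SessionStats(
            in_rate_per_lap=empty,
            out_rate_per_lap=empty,
            lap_times=mids,
            thirds_out=nan3,
            thirds_in=nan3,
            lap_corr_in=float("nan"),
            lap_corr_out=float("nan"),
            stability=float("nan"),
            spatial_info=0.0,
            field=None,
        )
    in_r, out_r = infield_outfield_rates(session, rmap, fld)
    si = spatial_information(rmap.mean_rate, rmap.occupancy)
    return SessionStats(
        in_rate_per_lap=in_r,
        out_rate_per_lap=out_r,
        lap_times=mids,
        thirds_out=session_thirds(out_r, mids, span),
        thirds_in=session_thirds(in_r, mids, span),
        lap_corr_in=lap_rate_correlation(in_r),
        lap_corr_out=lap_rate_correlation(out_r),
        stability=stability(rmap.lap_rate),
        spatial_info=si if si is not None else float("nan"),
        field=fld,
    )


def center_test(
    correlations: Sequence[float],
    direction: float | None = None,
    alpha_normality: float = 0.05,
) -> dict[str, float]:
    """Test whether the center of a correlation distribution is shifted
    from zero: one-tailed t if the sample passes Shapiro-Wilk normality
    at ``alpha_normality``, otherwise a sign test (binomial on nonzero
    signs).

    ``direction`` (+1 or -1) is the hypothesized shift and fixes the
    tail.  It should be set a priori — inferring it from the sample mean
    (the fallback when ``None``) doubles the type-I error rate of the
    one-tailed tests.
    """
    vals = np.asarray([c for c in correlations if np.isfinite(c)], dtype=float)
    if len(vals) < 3:
        raise ValueError("need >= 3 finite correlations")
    w, p_norm = sps.shapiro(vals)
    if direction is None:
        direction = 1.0 if vals.mean() >= 0 else -1.0
    direction = float(np.sign(direction)) or 1.0
    if p_norm > alpha_normality:
        alt = "greater" if direction > 0 else "less"
        res = sps.ttest_1samp(vals, 0.0, alternative=alt)
        return {"p": float(res.pvalue), "method": 1.0, "direction": direction, "n": len(vals)}
    nz = vals[vals != 0]
    k = int((nz > 0).sum()) if direction > 0 else int((nz < 0).sum())
    res = sps.binomtest(k, len(nz), 0.5, alternative="greater")
    return {"p": float(res.pvalue), "method": 0.0, "direction": direction, "n": len(vals)}


def thirds_anova(thirds: np.ndarray) -> dict[str, float]:
    """One-way repeated-measures ANOVA across session thirds (cells are
    the repeated factor).  Rows with missing thirds are dropped listwise;
    the retained n is reported."""
    arr = np.asarray(thirds, dtype=float)
    ok = np.all(np.isfinite(arr), axis=1)
    arr = arr[ok]
    n = arr.shape[0]
    if n < 3:
        raise ValueError("need >= 3 complete cells for the ANOVA")
    df = pd.DataFrame(
        {
            "cell": np.repeat(np.arange(n), 3),
            "third": np.tile(["start", "middle", "end"], n),
            "rate": arr.ravel(),
        }
    )
    from statsmodels.stats.anova import AnovaRM

    res = AnovaRM(df, depvar="rate", subject="cell", within=["third"]).fit()
    row = res.anova_table.iloc[0]
    return {"F": float(row["F Value"]), "p": float(row["Pr > F"]), "n": n}


def population_tests(
    per_cell: pd.DataFrame, metric: str = "out", direction: float | None = None
) -> dict[str, float]:
    """Population drift tests for one metric ('out' or 'in'):
    repeated-measures ANOVA on thirds and the center test on per-cell
    lap correlations.  ``per_cell`` needs columns third_start_<m>,
    third_middle_<m>, third_end_<m>, lap_corr_<m>.

    The center-test direction defaults to the a priori hypothesis for
    each metric: a decrease (-1) for out-of-field firing (reduced
    excitability), an increase (+1) for in-field firing (potentiation).
    """
    if direction is None:
        direction = -1.0 if metric == "out" else 1.0
    cols = [f"third_start_{metric}", f"third_middle_{metric}", f"third_end_{metric}"]
    anova = thirds_anova(per_cell[cols].to_numpy())
    ct = center_test(per_cell[f"lap_corr_{metric}"].to_numpy(), direction=direction)
    return {
        "anova_F": anova["F"],
        "anova_p": anova["p"],
        "anova_n": anova["n"],
        "center_p": ct["p"],
        "center_direction": ct["direction"],
        "center_method_ttest": ct["method"],
    }
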