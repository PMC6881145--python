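"""Intrinsic-excitability feature extraction from current-clamp sweeps.

All features follow the operational definitions used for in vivo CA1
recordings:

* spikes are detected where dV/dt (central differences) first reaches
  10 V/s on the rising phase; the voltage at that sample is the AP
  threshold;
* input resistance uses the voltage minimum within the first 150 ms of
  hyperpolarizing steps, referenced to a 50-ms pre-step baseline;
* sag ratio is the steady-state deflection (median of the final 50 ms of
  the step) divided by the minimum deflection within the first 150 ms,
  computed on baseline-subtracted voltages;
* the AHP is the minimum voltage within 50 ms after a spike threshold,
  counting only spikes whose window contains neither the next spike nor
  the end of the step;
* latency to first spike is measured on the maximal current steps;
* the burst index is the fraction of spikes participating in inter-spike
  intervals < 10 ms, taking the highest per-amplitude value among steps
  that evoke >= 5 spikes on average;
* Vm variance is the median variance over non-overlapping 5-s segments
  of spontaneous activity, with spikes blanked.

Per-cell aggregation: per-amplitude means over repeats, then the median
across amplitudes (Rin, sag) or the median across sweeps (threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .sweep import Sweep

DVDT_THRESHOLD_V_S = 10.0
RIN_WINDOW_MS = 150.0
SAG_STEADY_MS = 50.0
AHP_WINDOW_MS = 50.0
BURST_ISI_MS = 10.0
BURST_MIN_SPIKES = 5.0
BASELINE_MS = 50.0
VM_SEGMENT_S = 5.0
RS_FIT_START_MS = 5.0
RS_FIT_END_MS = 15.0
QC_VM_MAX_MV = -55.0
QC_RS_MAX_MOHM = 100.0
QC_SPIKE_AMP_MIN_MV = 40.0


@dataclass(frozen=True)
class SpikeEvent:
    """One detected action potential."""

    t_threshold: float  # ms
    v_threshold: float  # mV
    t_peak: float       # ms
    v_peak: float       # mV

    @property
    def amplitude(self) -> float:
        return self.v_peak - self.v_threshold


@dataclass
class CellFeatures:
    """Scalar intrinsic-excitability features for one cell at one timepoint.

    Fields that cannot be computed (e.g. no spikes) are ``None``.
    """

    rs: float | None = None                  # MOhm
    rin: float | None = None                 # MOhm
    sag_ratio: float | None = None
    ap_threshold: float | None = None        # mV
    ahp_min: float | None = None             # mV
    latency_ms: float | None = None          # ms
    burst_index: float | None = None
    vm_variance: float | None = None         # mV^2
    vm_rest: float | None = None             # mV
    spike_amplitude: float | None = None     # mV
    spike_counts: dict[float, float] = field(default_factory=dict)
    max_step_count: float | None = None      # mean spikes on maximal step
    flags: list[str] = field(default_factory=list)


def baseline(sweep: Sweep, window_ms: float = BASELINE_MS) -> float:
    """Mean Vm over the ``window_ms`` immediately preceding step onset."""
    n = min(int(round(window_ms / sweep.dt)), sweep.step_onset)
    if n < 1:
        raise ValueError("no pre-step samples available for baseline")
    return float(np.mean(sweep.v[sweep.step_onset - n : sweep.step_onset]))


def detect_spikes(
    sweep: Sweep,
    dvdt_thresh: float = DVDT_THRESHOLD_V_S,
    peak_min_mV: float = -20.0,
) -> list[SpikeEvent]:
    """Detect action potentials via the dV/dt criterion.

    dV/dt is computed by central differences (mV/ms == V/s).  The
    threshold point of each spike is the first sample of a rising phase
    where dV/dt >= ``dvdt_thresh``; the peak is the local voltage maximum
    that follows.  Candidates whose peak stays below ``peak_min_mV`` are
    discarded: fast subthreshold transients (large EPSPs, step onsets)
    can satisfy the slope criterion without being action potentials.
    Pass ``peak_min_mV=-inf`` for a pure slope criterion.
    """
    import warnings

    if sweep.dt > 0.2:
        warnings.warn(
            f"dt = {sweep.dt} ms is coarse for dV/dt-based spike detection",
            RuntimeWarning,
            stacklevel=2,
        )
    v = sweep.v
    n = len(v)
    if n < 3:
        return []
    dvdt = np.empty(n)
    dvdt[1:-1] = (v[2:] - v[:-2]) / (2.0 * sweep.dt)
    dvdt[0] = (v[1] - v[0]) / sweep.dt
    dvdt[-1] = (v[-1] - v[-2]) / sweep.dt

    above = dvdt >= dvdt_thresh
    # rising-phase entries: first sample of each run where dv/dt >= thresh
    starts = np.flatnonzero(above & ~np.roll(above, 1))
    if len(above) and above[0]:
        starts = np.unique(np.concatenate(([0], starts)))
    events: list[SpikeEvent] = []
    last_peak = -1
    for s in starts:
        if s <= last_peak:
            continue
        # follow the trace upward to the local maximum
        k = s
        while k + 1 < n and v[k + 1] >= v[k]:
            k += 1
        if v[k] <= v[s] or v[k] < peak_min_mV:
            continue
        events.append(
            SpikeEvent(
                t_threshold=s * sweep.dt,
                v_threshold=float(v[s]),
                t_peak=k * sweep.dt,
                v_peak=float(v[k]),
            )
        )
        last_peak = k
    return events


def spike_count(sweep: Sweep, dvdt_thresh: float = DVDT_THRESHOLD_V_S) -> int:
    """Number of spikes whose threshold falls within the step window."""
    on, off = sweep.step_onset * sweep.dt, sweep.step_offset * sweep.dt
    return sum(1 for e in detect_spikes(sweep, dvdt_thresh) if on <= e.t_threshold < off)


def _is_hyper(sweep: Sweep) -> bool:
    return sweep.step_amp < 0


def _group_by_amp(sweeps: Iterable[Sweep]) -> dict[float, list[Sweep]]:
    groups: dict[float, list[Sweep]] = {}
    for s in sweeps:
        groups.setdefault(s.step_amp, []).append(s)
    return groups


def estimate_series_resistance(hyper_sweeps: Sequence[Sweep]) -> float:
    """Series resistance (MOhm) from the instantaneous voltage drop.

    For each hyperpolarizing sweep a single exponential is fitted to the
    voltage 5-15 ms after step onset and extrapolated back to onset; the
    extrapolated value minus the pre-step baseline estimates the
    instantaneous (pipette) voltage drop.  The drops are regressed
    against injected current; the slope (mV/pA) converted to MOhm is Rs.
    Sweeps whose fit fails are flagged and skipped as long as two
    distinct amplitudes remain.
    """
    drops: list[float] = []
    amps: list[float] = []
    for s in hyper_sweeps:
        if not _is_hyper(s):
            continue
        i0 = s.step_onset + int(round(RS_FIT_START_MS / s.dt))
        i1 = s.step_onset + int(round(RS_FIT_END_MS / s.dt))
        t = (np.arange(i0, i1) - s.step_onset) * s.dt
        seg = s.v[i0:i1]
        base = baseline(s)

        def expdec(tt, A, tau, C):
            return A * np.exp(-tt / tau) + C

        try:
            p0 = (seg[0] - seg[-1], 10.0, seg[-1])
            popt, _ = curve_fit(
                expdec,
                t,
                seg,
                p0=p0,
                bounds=([-500.0, 0.5, -200.0], [500.0, 500.0, 100.0]),
                maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        v_at_onset = popt[0] + popt[2]
        drops.append(v_at_onset - base)
        amps.append(s.step_amp)
    if len(set(amps)) < 2:
        raise ValueError("series-resistance fit needs >= 2 distinct hyperpolarizing amplitudes")
    slope = np.polyfit(amps, drops, 1)[0]  # mV / pA == GOhm
    return float(slope * 1000.0)


def _mean_sweeps(sws: Sequence[Sweep]) -> list[Sweep]:
    """Average repeats into a single mean trace (per figure-style analysis
    of hyperpolarizing responses; averaging suppresses the noise bias of
    the within-window voltage minimum).  Sweeps must share dt, length and
    step window; if they do not, they are returned unaveraged.
    """
    first = sws[0]
    same = all(
        s.dt == first.dt
        and s.n_samples == first.n_samples
        and s.step_onset == first.step_onset
        and s.step_offset == first.step_offset
        for s in sws
    )
    if not same:
        return list(sws)
    v = np.mean([s.v for s in sws], axis=0)
    return [
        Sweep(
            dt=first.dt,
            v=v,
            i=first.i.copy(),
            step_onset=first.step_onset,
            step_offset=first.step_offset,
            step_amp=first.step_amp,
        )
    ]


def _min_deflection(sweep: Sweep, window_ms: float = RIN_WINDOW_MS) -> float:
    """Most negative baseline-subtracted voltage within ``window_ms`` of onset."""
    base = baseline(sweep)
    i1 = min(sweep.step_onset + int(round(window_ms / sweep.dt)), sweep.step_offset)
    return float(np.min(sweep.v[sweep.step_onset : i1]) - base)


def input_resistance(hyper_sweeps: Sequence[Sweep], average_repeats: bool = True) -> float:
    """Input resistance (MOhm): minimum deflection within 150 ms of onset
    over step current; repeats averaged into a mean trace per amplitude,
    median across amplitudes."""
    groups = _group_by_amp(s for s in hyper_sweeps if _is_hyper(s))
    if not groups:
        raise ValueError("input resistance requires hyperpolarizing sweeps")
    per_amp = []
    for amp, sws in groups.items():
        if average_repeats:
            sws = _mean_sweeps(sws)
        rins = [_min_deflection(s) / amp * 1000.0 for s in sws]  # MOhm, positive
        per_amp.append(float(np.mean(rins)))
    return float(np.median(per_amp))


def sag_ratio(hyper_sweeps: Sequence[Sweep], average_repeats: bool = True) -> float:
    """Sag ratio: steady-state deflection (median of final 50 ms of the
    step) over minimum deflection within the first 150 ms, both
    baseline-subtracted; repeats averaged into a mean trace per
    amplitude, median across amplitudes.  Values below 1 indicate
    h-current sag."""
    groups = _group_by_amp(s for s in hyper_sweeps if _is_hyper(s))
    if not groups:
        raise ValueError("sag ratio requires hyperpolarizing sweeps")
    per_amp = []
    for amp, sws in groups.items():
        if average_repeats:
            sws = _mean_sweeps(sws)
        ratios = []
        for s in sws:
            base = baseline(s)
            n50 = int(round(SAG_STEADY_MS / s.dt))
            steady = float(np.median(s.v[s.step_offset - n50 : s.step_offset]) - base)
            vmin = _min_deflection(s)
            if vmin == 0.0:
                raise ZeroDivisionError("zero minimum deflection; sag ratio undefined")
            ratios.append(steady / vmin)
        per_amp.append(float(np.mean(ratios)))
    return float(np.median(per_amp))


def ap_threshold_feature(depol_sweeps: Sequence[Sweep]) -> float | None:
    """Median threshold voltage of the first spike across depolarizing sweeps."""
    firsts = []
    for s in depol_sweeps:
        if s.step_amp <= 0:
            continue
        events = _step_spikes(s)
        if events:
            firsts.append(events[0].v_threshold)
    if not firsts:
        return None
    return float(np.median(firsts))


def _step_spikes(sweep: Sweep) -> list[SpikeEvent]:
    on, off = sweep.step_onset * sweep.dt, sweep.step_offset * sweep.dt
    return [e for e in detect_spikes(sweep) if on <= e.t_threshold < off]


def ahp_feature(depol_sweeps: Sequence[Sweep]) -> float | None:
    """Mean afterhyperpolarization minimum (mV) over eligible spikes.

    Per spike, the minimum voltage in the 50 ms after its threshold; a
    spike is eligible only if both the next spike's threshold and the
    step offset fall outside that window.
    """
    mins = []
    for s in depol_sweeps:
        if s.step_amp <= 0:
            continue
        events = _step_spikes(s)
        t_off = s.step_offset * s.dt
        for j, e in enumerate(events):
            w_end = e.t_threshold + AHP_WINDOW_MS
            if w_end > t_off:
                continue
            if j + 1 < len(events) and events[j + 1].t_threshold <= w_end:
                continue
            i0 = int(round(e.t_threshold / s.dt)) + 1
            i1 = int(round(w_end / s.dt)) + 1
            mins.append(float(np.min(s.v[i0:i1])))
    if not mins:
        return None
    return float(np.mean(mins))


def first_spike_latency(max_amp_sweeps: Sequence[Sweep]) -> float | None:
    """Mean latency (ms) from step onset to the first spike threshold on
    the maximal current steps; zero-spike sweeps are excluded."""
    lats = []
    for s in max_amp_sweeps:
        events = _step_spikes(s)
        if events:
            lats.append(events[0].t_threshold - s.step_onset * s.dt)
    if not lats:
        return None
    return float(np.mean(lats))


def _burst_fraction(spike_times: np.ndarray, isi_ms: float = BURST_ISI_MS) -> float | None:
    if len(spike_times) == 0:
        return None
    if len(spike_times) == 1:
        return 0.0
    isi = np.diff(spike_times)
    short = isi < isi_ms
    in_burst = np.zeros(len(spike_times), dtype=bool)
    in_burst[:-1] |= short
    in_burst[1:] |= short
    return float(in_burst.sum() / len(spike_times))


def burst_index(
    depol_sweeps: Sequence[Sweep],
    mode: str = "per-sweep",
) -> float | None:
    """Fraction of spikes in bursts (ISI < 10 ms).

    Per amplitude, either the mean of per-sweep fractions (default) or
    the fraction over spikes pooled across repeats (``mode='pooled'``).
    The cell value is the highest per-amplitude value among amplitudes
    that evoke an average of >= 5 spikes; ``None`` if no amplitude does.
    """
    if mode not in ("per-sweep", "pooled"):
        raise ValueError("mode must be 'per-sweep' or 'pooled'")
    groups = _group_by_amp(s for s in depol_sweeps if s.step_amp > 0)
    candidates = []
    for amp, sws in groups.items():
        trains = [np.array([e.t_threshold for e in _step_spikes(s)]) for s in sws]
        mean_count = float(np.mean([len(t) for t in trains]))
        if mean_count < BURST_MIN_SPIKES:
            continue
        if mode == "pooled":
            fracs = [_burst_fraction(np.concatenate([t for t in trains if len(t)]))]
        else:
            fracs = [f for t in trains if (f := _burst_fraction(t)) is not None]
        if fracs:
            candidates.append(float(np.mean(fracs)))
    if not candidates:
        return None
    return max(candidates)


def vm_variance(
    trace: Sweep | np.ndarray,
    dt_ms: float | None = None,
    segment_s: float = VM_SEGMENT_S,
    blank_spikes: bool = True,
) -> float:
    """Median Vm variance (mV^2) over non-overlapping segments.

    Spikes are excised by blanking +/-5 ms around detected peaks before
    the variance is computed.
    """
    if isinstance(trace, Sweep):
        v = trace.v
        dt = trace.dt
        sw = trace
    else:
        if dt_ms is None:
            raise ValueError("dt_ms required when passing a bare array")
        v = np.asarray(trace, dtype=float)
        dt = dt_ms
        sw = Sweep(dt=dt, v=v, i=np.zeros_like(v), step_onset=0, step_offset=len(v), step_amp=0.0)
    seg_n = int(round(segment_s * 1000.0 / dt))
    if len(v) < seg_n:
        raise ValueError("trace shorter than one segment")
    keep = np.ones(len(v), dtype=bool)
    if blank_spikes:
        for e in detect_spikes(sw):
            pk = int(round(e.t_peak / dt))
            i0 = max(pk - int(round(5.0 / dt)), 0)
            i1 = min(pk + int(round(5.0 / dt)) + 1, len(v))
            keep[i0:i1] = False
    variances = []
    for k in range(len(v) // seg_n):
        seg = v[k * seg_n : (k + 1) * seg_n][keep[k * seg_n : (k + 1) * seg_n]]
        if len(seg) > 1:
            variances.append(float(np.var(seg)))
    return float(np.median(variances))


def qc_pass(features: CellFeatures) -> tuple[bool, list[str]]:
    """Inclusion criteria: resting Vm < -55 mV, Rs < 100 MOhm, spike
    amplitude > 40 mV (all strict).  Returns (passed, failed-criteria)."""
    reasons = []
    if features.vm_rest is None or not features.vm_rest < QC_VM_MAX_MV:
        reasons.append("vm_rest")
    if features.rs is None or not features.rs < QC_RS_MAX_MOHM:
        reasons.append("rs")
    if features.spike_amplitude is None or not features.spike_amplitude > QC_SPIKE_AMP_MIN_MV:
        reasons.append("spike_amplitude")
    return (len(reasons) == 0, reasons)


def extract_features(sweeps: Sequence[Sweep], spont: Sweep | None = None) -> CellFeatures:
    """Compute the full feature set for one cell block.

    ``sweeps`` holds the step-protocol trials (hyperpolarizing and
    depolarizing, all repeats); ``spont`` is an optional spontaneous
    trace for the Vm-variance estimate.  Features whose sweep class is
    missing are left ``None`` and noted in ``flags``.
    """
    feats = CellFeatures()
    hyper = [s for s in sweeps if s.step_amp < 0]
    depol = [s for s in sweeps if s.step_amp > 0]

    if hyper:
        feats.rin = input_resistance(hyper)
        feats.sag_ratio = sag_ratio(hyper)
        try:
            feats.rs = estimate_series_resistance(hyper)
        except ValueError:
            feats.flags.append("rs_failed")
        feats.vm_rest = float(np.median([baseline(s) for s in sweeps]))
    else:
        feats.flags.append("no_hyperpolarizing_sweeps")
        if sweeps:
            feats.vm_rest = float(np.median([baseline(s) for s in sweeps]))

    if depol:
        feats.ap_threshold = ap_threshold_feature(depol)
        feats.ahp_min = ahp_feature(depol)
        feats.burst_index = burst_index(depol)
        groups = _group_by_amp(depol)
        feats.spike_counts = {
            amp: float(np.mean([spike_count(s) for s in sws])) for amp, sws in groups.items()
        }
        max_amp = max(groups)
        feats.max_step_count = feats.spike_counts[max_amp]
        feats.latency_ms = first_spike_latency(groups[max_amp])
        amps = []
        for s in depol:
            events = _step_spikes(s)
            if events:
                amps.append(events[0].amplitude)
        feats.spike_amplitude = float(np.median(amps)) if amps else None
    else:
        feats.flags.append("no_depolarizing_sweeps")

    if spont is not None:
        feats.vm_variance = vm_variance(spont)
    return feats
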