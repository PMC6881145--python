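"""Command-current waveform construction: steps and theta-burst trains."""

from __future__ import annotations

import numpy as np

from .params import EPSCShape, StimulusProtocol, TBSSpec


class InvalidProtocolError(ValueError):
    """Raised when a stimulus specification cannot produce a waveform."""


def epsc_kernel(shape: EPSCShape, dt: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to peak at
    ``shape.amplitude_pA``.

    The kernel is truncated at 8 decay time constants, where the residual
    amplitude is below 0.04% of peak.
    """
    if dt <= 0:
        raise InvalidProtocolError("dt must be positive")
    t = np.arange(0.0, 8.0 * shape.decay_ms, dt)
    w = np.exp(-t / shape.decay_ms) - np.exp(-t / shape.rise_ms)
    peak = w.max()
    if peak <= 0:
        raise InvalidProtocolError("degenerate EPSC kernel")
    return shape.amplitude_pA * w / peak


def tbs_pulse_onsets_ms(spec: TBSSpec, within_series: bool = True) -> np.ndarray:
    """Onset times (ms) of every pulse in one series of the burst protocol.

    Pulses within a burst are spaced at ``1000 / intra_burst_hz`` ms;
    burst onsets repeat at ``1000 / burst_hz`` ms.
    """
    ipi = 1000.0 / spec.intra_burst_hz
    ibi = 1000.0 / spec.burst_hz
    onsets = []
    for b in range(spec.bursts_per_series):
        for p in range(spec.pulses_per_burst):
            onsets.append(b * ibi + p * ipi)
    return np.asarray(onsets)


def build_series_waveform(spec: TBSSpec, dt: float, tail_ms: float = 100.0) -> np.ndarray:
    """Command current (pA) for a single series of the burst protocol."""
    if dt <= 0:
        raise InvalidProtocolError("dt must be positive")
    onsets = tbs_pulse_onsets_ms(spec)
    kernel = epsc_kernel(spec.epsc, dt)
    n = int(round((onsets[-1] + 8.0 * spec.epsc.decay_ms + tail_ms) / dt))
    out = np.zeros(n)
    for t0 in onsets:
        i0 = int(round(t0 / dt))
        seg = min(len(kernel), n - i0)
        out[i0 : i0 + seg] += kernel[:seg]
    return out


def build_tbs_waveform(proto: StimulusProtocol, dt: float) -> np.ndarray:
    """Full induction command current including inter-series gaps.

    Returns a single trace containing ``total_pulses`` EPSC-shaped events;
    the trace is zero outside events.  With ``n_series == 0`` an all-zero
    trace of one inter-series interval is returned.
    """
    spec = proto.tbs
    if dt <= 0:
        raise InvalidProtocolError("dt must be positive")
    if spec.n_series > 0 and spec.pulses_per_burst * spec.bursts_per_series == 0:
        raise InvalidProtocolError("zero pulses per series")
    gap_n = int(round(spec.inter_series_s * 1000.0 / dt))
    if spec.n_series == 0:
        return np.zeros(gap_n)
    series = build_series_waveform(spec, dt)
    parts = []
    for k in range(spec.n_series):
        parts.append(series)
        if k < spec.n_series - 1:
            parts.append(np.zeros(max(gap_n - len(series), 0)))
    return np.concatenate(parts)


def build_step_waveform(
    amp_pA: float, proto: StimulusProtocol, dt: float
) -> tuple[np.ndarray, int, int]:
    """Command current for one testing step; returns (trace, onset, offset)
    sample indices of the step."""
    if dt <= 0:
        raise InvalidProtocolError("dt must be positive")
    onset = int(round(proto.pre_ms / dt))
    dur = int(round(proto.step_duration_ms / dt))
    post = int(round(proto.post_ms / dt))
    i = np.zeros(onset + dur + post)
    i[onset : onset + dur] = amp_pA
    return i, onset, onset + dur
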