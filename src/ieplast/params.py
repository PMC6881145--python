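"""Parameter containers for the neuron model, stimulation protocols and
synthetic place-cell sessions.

Units follow patch-clamp conventions throughout: capacitance in pF,
conductance in nS, voltage in mV, current in pA, time in ms (except
place-session quantities, which use s, cm and Hz).  With these units
``nS * mV = pA`` and ``pF / nS = ms``, so no conversion factors appear in
the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence


@dataclass(frozen=True)
class EPSCShape:
    """Difference-of-exponentials synaptic-like current waveform."""

    rise_ms: float = 0.5
    decay_ms: float = 3.0
    amplitude_pA: float = 1050.0

    def __post_init__(self) -> None:
        if self.rise_ms <= 0 or self.decay_ms <= self.rise_ms:
            raise ValueError("EPSC shape requires 0 < rise < decay")


@dataclass(frozen=True)
class TBSSpec:
    """Theta-burst stimulation: bursts of EPSC-like pulses at 100 Hz,
    repeated at theta frequency, in several series."""

    pulses_per_burst: int = 10
    intra_burst_hz: float = 100.0
    bursts_per_series: int = 10
    burst_hz: float = 5.0
    n_series: int = 3
    inter_series_s: float = 15.0
    epsc: EPSCShape = field(default_factory=EPSCShape)

    @property
    def total_pulses(self) -> int:
        return self.pulses_per_burst * self.bursts_per_series * self.n_series


@dataclass(frozen=True)
class StimulusProtocol:
    """Current-step testing protocol plus the TBS induction stimulus.

    Defaults are the standard in vivo testing protocol: 300-ms steps at
    1.5-s intervals, hyperpolarizing steps at -300/-250/-200 pA, a range
    of depolarizing steps, 10 repeats, holding at -60 mV.
    """

    step_duration_ms: float = 300.0
    inter_sweep_interval_ms: float = 1500.0
    hyper_amps_pA: tuple[float, ...] = (-300.0, -250.0, -200.0)
    depol_amps_pA: tuple[float, ...] = (300.0, 350.0, 400.0, 450.0, 500.0, 550.0)
    n_repeats: int = 10
    holding_target_mV: float = -60.0
    pre_ms: float = 100.0
    post_ms: float = 100.0
    tbs: TBSSpec = field(default_factory=TBSSpec)

    def __post_init__(self) -> None:
        if self.step_duration_ms <= 0:
            raise ValueError("step_duration_ms must be positive")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    @property
    def max_depol_amp(self) -> float:
        return max(self.depol_amps_pA)


@dataclass(frozen=True)
class NeuronParams:
    """Single-compartment exponential integrate-and-fire neuron with an
    h-current (sag) and a slowly inactivating D-type potassium current.

    The D-current gates use a fast activation variable and a slow
    inactivation variable; their voltage dependence overlaps near the
    holding potential so a small standing current contributes to the
    resting conductance, as expected for axonal Kv1.1.
    """

    Cm: float = 200.0          # pF
    gL: float = 13.5           # nS
    EL: float = -65.0          # mV
    VT: float = -50.0          # mV, exponential spike-initiation threshold
    DeltaT: float = 2.0        # mV, spike slope factor
    Vreset: float = -60.0      # mV
    t_ref: float = 2.0         # ms
    v_cut: float = 0.0         # mV, upstroke voltage triggering reset
    v_peak: float = 35.0       # mV, recorded spike-peak sample

    gh_max: float = 8.0       # nS
    Eh: float = -30.0          # mV
    h_vhalf: float = -80.0     # mV  (activates with hyperpolarization)
    h_k: float = 8.0           # mV
    h_tau: float = 80.0        # ms

    gD_max: float = 30.0       # nS
    EK: float = -90.0          # mV
    Da_vhalf: float = -47.0    # mV  (activation)
    Da_k: float = 8.0          # mV
    Da_tau: float = 6.0        # ms
    Di_vhalf: float = -55.0    # mV  (inactivation)
    Di_k: float = 7.0          # mV
    Di_tau: float = 600.0      # ms (slow)

    noise_sd: float = 2.0      # mV, stationary Vm fluctuation amplitude
    noise_tau: float = 3.0     # ms, correlation time of the noise current

    def __post_init__(self) -> None:
        if self.Cm <= 0:
            raise ValueError("Cm must be positive")
        for name in ("gL", "gh_max", "gD_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")
        if self.Di_tau <= self.Da_tau:
            raise ValueError("D-current inactivation must be slower than activation")

    def with_updates(self, **kwargs) -> "NeuronParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PlasticityRule:
    """Spike-count-dependent homeostatic rule.

    Each spike evoked during the induction burst increments the D-type
    potassium conductance by a fraction ``alpha_D`` and decrements the
    h-conductance by ``alpha_h``, with saturation at ``cap_D``/``cap_h``.
    This is a phenomenological transfer function calibrated to reproduce
    group-level effect sizes, not a mechanistic claim.
    """

    alpha_D: float = 0.0028    # fractional gD increase per evoked spike
    alpha_h: float = 0.0010    # fractional gh decrease per evoked spike
    cap_D: float = 1.2         # max fractional gD increase
    cap_h: float = 0.35        # max fractional gh decrease

    def __post_init__(self) -> None:
        if self.alpha_D < 0 or self.alpha_h < 0:
            raise ValueError("plasticity rates must be non-negative")
        if not 0 <= self.cap_h <= 1:
            raise ValueError("cap_h must lie in [0, 1] so gh stays non-negative")
        if self.cap_D < 0:
            raise ValueError("cap_D must be non-negative")

    def scaled(self, factor: float) -> "PlasticityRule":
        return replace(self, alpha_D=self.alpha_D * factor, alpha_h=self.alpha_h * factor)


@dataclass(frozen=True)
class PlaceSessionParams:
    """Synthetic linear-track place-cell session.

    A cell fires from a truncated-Gaussian in-field bump riding on a
    uniform out-of-field baseline; both components scale geometrically
    across laps (``in_field_gain_per_lap`` and ``drift_per_lap``) to
    emulate within-session potentiation and excitability drift.
    """

    track_length_cm: float = 200.0
    n_laps: int = 30
    field_center_cm: float = 100.0
    field_width_cm: float = 40.0
    peak_rate_in_hz: float = 8.0
    base_rate_out_hz: float = 1.6
    drift_per_lap: float = 1.0
    in_field_gain_per_lap: float = 1.0
    speed_cm_s: float = 20.0
    dt_s: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_rate_in_hz < 0 or self.base_rate_out_hz < 0:
            raise ValueError("rates must be non-negative")
        if not 0 < self.field_width_cm < self.track_length_cm:
            raise ValueError("field width must lie inside the track")
        if self.drift_per_lap <= 0 or self.in_field_gain_per_lap <= 0:
            raise ValueError("drift factors must be positive")
        if self.speed_cm_s <= 0 or self.dt_s <= 0 or self.n_laps < 1:
            raise ValueError("speed, dt and lap count must be positive")


def heterogeneous_params(
    base: NeuronParams,
    rng,
    cv: float = 0.10,
    jitter_fields: Sequence[str] = ("Cm", "gL", "gh_max", "gD_max"),
) -> NeuronParams:
    """Draw a cell-specific parameter set: log-normal jitter (default 10%
    CV) around the population defaults on the passive/conductance fields."""
    import math

    s = math.sqrt(math.log(1.0 + cv**2))
    updates = {}
    for name in jitter_fields:
        factor = math.exp(rng.normal(-0.5 * s**2, s))
        updates[name] = getattr(base, name) * factor
    return base.with_updates(**updates)
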