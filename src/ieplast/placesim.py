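"""Synthetic place-cell sessions on a linear track.

The virtual animal runs back and forth at constant speed; one direction
of running is modelled (each direction of a real session is analyzed
independently, so a session here corresponds to one direction).  Spiking
is an inhomogeneous Poisson process whose rate is a truncated-Gaussian
place field riding on a uniform out-of-field baseline:

    rate(x, lap) = base * drift**lap
                 + peak * gain**lap * exp(-(x - c)^2 / (2 sigma^2))
                   for |x - c| <= width/2   (0 outside the field)

with sigma = width / 4, so the bump falls to ~13.5% of its peak at the
field edge.  ``drift_per_lap`` < 1 produces the multiplicative lap-to-lap
decay of out-of-field firing that an excitability decrease would cause;
``in_field_gain_per_lap`` > 1 produces the within-field potentiation-like
increase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import PlaceSessionParams


@dataclass
class PlaceSession:
    """Spike times, position samples and lap structure for one cell."""

    spike_times: np.ndarray          # s
    t: np.ndarray                    # s, position timestamps
    x: np.ndarray                    # cm
    laps: list[tuple[float, float, int]]   # (start s, end s, direction +1/-1)
    track_length: float              # cm
    condition: str = "novel"
    params: PlaceSessionParams | None = None

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def n_laps(self) -> int:
        return len(self.laps)


def field_rate(x: np.ndarray, p: PlaceSessionParams, lap: int) -> np.ndarray:
    """Firing rate (Hz) at positions ``x`` on a given lap (0-based)."""
    sigma = p.field_width_cm / 4.0
    bump = np.exp(-((x - p.field_center_cm) ** 2) / (2.0 * sigma**2))
    bump = np.where(np.abs(x - p.field_center_cm) <= p.field_width_cm / 2.0, bump, 0.0)
    rate = (
        p.base_rate_out_hz * p.drift_per_lap**lap
        + p.peak_rate_in_hz * p.in_field_gain_per_lap**lap * bump
    )
    return rate


def simulate_place_session(p: PlaceSessionParams, condition: str = "novel") -> PlaceSession:
    """Simulate one cell's session; reproducible given ``p.seed``.

    The trajectory is a triangle wave (constant speed, instantaneous
    turnarounds).  Only outbound laps carry the modelled rate (one
    direction analyzed); return laps are traversed silently and excluded
    from the lap list.
    """
    rng = np.random.Generator(np.random.Philox(p.seed))
    lap_dur = p.track_length_cm / p.speed_cm_s
    n_steps_lap = int(round(lap_dur / p.dt_s))
    ts, xs, spikes, laps = [], [], [], []
    t0 = 0.0
    for lap in range(p.n_laps):
        tt = t0 + np.arange(n_steps_lap) * p.dt_s
        xx = np.arange(n_steps_lap) * p.dt_s * p.speed_cm_s
        rate = field_rate(xx, p, lap)
        counts = rng.poisson(rate * p.dt_s)
        base_t = np.repeat(tt, counts)
        if len(base_t):
            spikes.append(base_t + rng.uniform(0.0, p.dt_s, size=len(base_t)))
        ts.append(tt)
        xs.append(xx)
        laps.append((float(tt[0]), float(tt[-1] + p.dt_s), 1))
        # silent return run, half speed of bookkeeping not needed: same duration
        tt_back = t0 + lap_dur + np.arange(n_steps_lap) * p.dt_s
        xx_back = p.track_length_cm - np.arange(n_steps_lap) * p.dt_s * p.speed_cm_s
        ts.append(tt_back)
        xs.append(xx_back)
        t0 += 2.0 * lap_dur
    return PlaceSession(
        spike_times=np.sort(np.concatenate(spikes)) if spikes else np.empty(0),
        t=np.concatenate(ts),
        x=np.concatenate(xs),
        laps=laps,
        track_length=p.track_length_cm,
        condition=condition,
        params=p,
    )
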