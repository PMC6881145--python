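"""The Sweep container: one current-clamp trial (voltage + command)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Sweep:
    """Sampled membrane voltage and command current for a single trial.

    ``step_onset``/``step_offset`` are sample indices delimiting the
    current step (offset is exclusive); ``step_amp`` is the step
    amplitude in pA (0 for non-step protocols such as induction bursts).
    """

    dt: float                      # ms per sample
    v: np.ndarray                  # mV
    i: np.ndarray                  # pA
    step_onset: int
    step_offset: int
    step_amp: float

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=np.float64)
        self.i = np.asarray(self.i, dtype=np.float64)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.v.shape != self.i.shape or self.v.ndim != 1:
            raise ValueError("voltage and current traces must be 1-D and equal length")
        if not 0 <= self.step_onset < self.step_offset <= len(self.v):
            raise ValueError("step window indices out of order or out of bounds")

    @property
    def t(self) -> np.ndarray:
        """Time axis in ms."""
        return np.arange(len(self.v)) * self.dt

    @property
    def n_samples(self) -> int:
        return len(self.v)
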