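"""Shared fixtures: small synthetic sweeps and cheap simulation configs."""

from __future__ import annotations

import numpy as np
import pytest

from ieplast.params import NeuronParams, StimulusProtocol
from ieplast.sweep import Sweep


@pytest.fixture(scope="session")
def proto() -> StimulusProtocol:
    return StimulusProtocol()


@pytest.fixture(scope="session")
def quiet_params() -> NeuronParams:
    """Noise-free default cell."""
    return NeuronParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def passive_params() -> NeuronParams:
    """Pure RC cell: no gated conductances, no noise."""
    return NeuronParams(gh_max=0.0, gD_max=0.0, noise_sd=0.0)


def make_step_sweep(
    v_fn,
    dt: float = 0.1,
    pre_ms: float = 100.0,
    step_ms: float = 300.0,
    post_ms: float = 100.0,
    amp: float = -250.0,
) -> Sweep:
    """Construct a sweep whose step-window voltage course is given by
    ``v_fn(t_ms_from_onset)``; pre/post are held at the baseline value."""
    n_pre = int(round(pre_ms / dt))
    n_step = int(round(step_ms / dt))
    n_post = int(round(post_ms / dt))
    t_step = np.arange(n_step) * dt
    v_step = np.asarray(v_fn(t_step), dtype=float)
    vb = getattr(v_fn, "baseline", -60.0)
    v = np.concatenate([np.full(n_pre, vb), v_step, np.full(n_post, vb)])
    i = np.concatenate([np.zeros(n_pre), np.full(n_step, amp), np.zeros(n_post)])
    return Sweep(dt=dt, v=v, i=i, step_onset=n_pre, step_offset=n_pre + n_step, step_amp=amp)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.Philox(1234))
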