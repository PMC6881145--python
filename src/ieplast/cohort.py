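"""Synthetic cohorts: cells, induction conditions and recording sessions.

A cohort emulates the design of an induction experiment: every cell is
tested with the full step protocol before induction ("pre") and again at
10, 20 and 30 min.  Cells in burst-stimulated conditions additionally
receive the theta-burst protocol immediately after the pre block, and
their conductances are updated by the spike-count-dependent plasticity
rule; the expressed change ramps to its full value by 20 min.

Condition regimes
-----------------
``TBS``      burst stimulation, full plasticity rule
``control``  no burst stimulation, no plasticity
``BAPTA``    burst stimulation, plasticity rule silenced (calcium
             chelation blocks induction)
``MK801``    burst stimulation, full rule (NMDA-receptor block does not
             affect induction)
``ZD``       h-conductance zeroed (h-current blocker), otherwise full rule
``DTX``      D-type conductance and its plasticity rate reduced to 40%
             (Kv1.1 block); cells fire more during the burst

Per-cell heterogeneity: log-normal (10% CV) jitter on Cm, gL, gh_max and
gD_max; the depolarizing step range is re-centred on each cell's
rheobase (mirroring the experimenters' per-cell adjustment of step
amplitudes); the burst EPSC amplitude and a multiplicative jitter on the
plasticity rates vary across cells so that evoked spike counts and
expressed effect sizes are heterogeneous at the group level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .params import (
    EPSCShape,
    NeuronParams,
    PlasticityRule,
    StimulusProtocol,
    heterogeneous_params,
)
from .plasticity import apply_plasticity
from .neuron import simulate_spontaneous, simulate_sweep, simulate_tbs
from .sweep import Sweep

CONDITIONS = ("TBS", "control", "BAPTA", "MK801", "ZD", "DTX")
TIMEPOINTS = ("pre", "10", "20", "30")

#: expressed fraction of the full conductance change at each timepoint
EXPRESSION_SCHEDULE: Mapping[str, float] = {"pre": 0.0, "10": 0.7, "20": 1.0, "30": 1.0}


class UnknownConditionError(ValueError):
    pass


@dataclass
class CellSession:
    """All recorded data for one cell across the experiment."""

    cell_id: str
    condition: str
    params_pre: NeuronParams
    protocol: StimulusProtocol
    blocks: dict[str, list[Sweep]] = field(default_factory=dict)
    spont: dict[str, Sweep] = field(default_factory=dict)
    tbs_sweeps: list[Sweep] = field(default_factory=list)
    tbs_spike_count: int = 0
    response_gain: float = 1.0


def _condition_params(
    condition: str, base: NeuronParams, rule: PlasticityRule
) -> tuple[NeuronParams, PlasticityRule, bool]:
    """Map a condition label to (cell params, effective rule, tbs applied)."""
    if condition == "TBS":
        return base, rule, True
    if condition == "control":
        return base, rule.scaled(0.0), False
    if condition == "BAPTA":
        return base, rule.scaled(0.0), True
    if condition == "MK801":
        return base, rule, True
    if condition == "ZD":
        return base.with_updates(gh_max=0.0), rule, True
    if condition == "DTX":
        reduced = base.with_updates(gD_max=0.4 * base.gD_max)
        return reduced, replace(rule, alpha_D=0.4 * rule.alpha_D), True
    raise UnknownConditionError(
        f"unknown condition {condition!r}; expected one of {CONDITIONS}"
    )


def find_rheobase(
    params: NeuronParams,
    proto: StimulusProtocol,
    dt: float = 0.025,
    grid_pA: Sequence[float] | None = None,
) -> float:
    """Smallest step current on a 50-pA grid evoking at least one spike on
    a noise-free sweep."""
    from .features import spike_count

    quiet = params.with_updates(noise_sd=0.0)
    if grid_pA is None:
        grid_pA = np.arange(100.0, 1050.0, 50.0)
    grid = np.asarray(grid_pA, dtype=float)

    def fires(amp: float) -> bool:
        return spike_count(simulate_sweep(quiet, amp, proto, dt=dt, seed=0)) > 0

    # noise-free spiking is monotone in step current: bisect on the grid
    lo, hi = 0, len(grid) - 1
    if fires(grid[lo]):
        return float(grid[lo])
    if not fires(grid[hi]):
        return float(grid[hi])
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if fires(grid[mid]):
            hi = mid
        else:
            lo = mid
    return float(grid[hi])


def adapted_protocol(
    params: NeuronParams,
    proto: StimulusProtocol,
    rng: np.random.Generator,
    epsc_amp_mean: float = 1050.0,
    epsc_amp_cv: float = 0.35,
    dt: float = 0.025,
) -> StimulusProtocol:
    """Per-cell protocol emulating the experimenters' manual adjustment.

    Depolarizing steps start near the cell's rheobase but with a coarse
    random offset, spacing and step count (4-6 steps, 40-75 pA apart),
    the way step ranges are chosen by eye from a cell's initial
    responses.  This placement variability is what gives the pooled
    normalized input-output curves their realistic between-cell scatter.
    The burst EPSC amplitude is cell-specific (log-normal, 35% CV),
    spreading evoked spike counts widely across cells.
    """
    rheo = find_rheobase(params, proto, dt=dt)
    offset = float(rng.choice([-50.0, 0.0, 50.0]))
    spacing = float(rng.choice([40.0, 50.0, 60.0, 75.0]))
    n_steps = int(rng.choice([4, 5, 6]))
    depol = tuple(rheo + offset + spacing * k for k in range(n_steps))
    s = float(np.sqrt(np.log(1.0 + epsc_amp_cv**2)))
    amp = float(epsc_amp_mean * np.exp(rng.normal(-0.5 * s**2, s)))
    tbs = replace(proto.tbs, epsc=replace(proto.tbs.epsc, amplitude_pA=amp))
    return replace(proto, depol_amps_pA=depol, tbs=tbs)


def _record_block(
    params: NeuronParams,
    proto: StimulusProtocol,
    rng: np.random.Generator,
    dt: float,
) -> list[Sweep]:
    sweeps = []
    for amp in tuple(proto.hyper_amps_pA) + tuple(proto.depol_amps_pA):
        for _ in range(proto.n_repeats):
            sweeps.append(simulate_sweep(params, amp, proto, dt=dt, seed=rng))
    return sweeps


def generate_cell(
    cell_id: str,
    condition: str,
    rule: PlasticityRule,
    seed_seq: np.random.SeedSequence,
    base_params: NeuronParams | None = None,
    proto: StimulusProtocol | None = None,
    dt: float = 0.025,
    heterogeneity_cv: float = 0.10,
    response_jitter_sd: float = 0.60,
    include_spontaneous: bool = True,
    spont_duration_s: float = 25.0,
    timepoints: Sequence[str] = TIMEPOINTS,
    expression: Mapping[str, float] = EXPRESSION_SCHEDULE,
) -> CellSession:
    """Simulate one cell's full experiment."""
    base_params = base_params or NeuronParams()
    proto = proto or StimulusProtocol()
    rng = np.random.Generator(np.random.Philox(seed_seq))

    cell_base = heterogeneous_params(base_params, rng, cv=heterogeneity_cv)
    params, eff_rule, tbs_applied = _condition_params(condition, cell_base, rule)
    cell_proto = adapted_protocol(params, proto, rng, dt=dt)

    gain = float(np.exp(rng.normal(-0.5 * response_jitter_sd**2, response_jitter_sd)))
    eff_rule = eff_rule.scaled(gain)

    session = CellSession(
        cell_id=cell_id,
        condition=condition,
        params_pre=params,
        protocol=cell_proto,
        response_gain=gain,
    )
    session.blocks["pre"] = _record_block(params, cell_proto, rng, dt)
    if include_spontaneous:
        session.spont["pre"] = simulate_spontaneous(
            params, spont_duration_s * 1000.0, cell_proto, seed=rng
        )

    if tbs_applied:
        session.tbs_sweeps, session.tbs_spike_count = simulate_tbs(
            params, cell_proto, dt=dt, seed=rng
        )

    for tp in timepoints:
        if tp == "pre":
            continue
        frac = expression.get(tp, 1.0)
        p_tp = apply_plasticity(params, eff_rule, session.tbs_spike_count, fraction=frac)
        session.blocks[tp] = _record_block(p_tp, cell_proto, rng, dt)
        if include_spontaneous:
            session.spont[tp] = simulate_spontaneous(
                p_tp, spont_duration_s * 1000.0, cell_proto, seed=rng
            )
    return session


def iter_cohort(
    n_cells: int,
    condition: str,
    rule: PlasticityRule | None = None,
    seed: int = 0,
    **cell_kwargs,
) -> Iterator[CellSession]:
    """Yield cells one at a time (memory-friendly for large cohorts)."""
    if condition not in CONDITIONS:
        raise UnknownConditionError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    rule = rule or PlasticityRule()
    children = np.random.SeedSequence(seed).spawn(n_cells)
    for k, ss in enumerate(children):
        yield generate_cell(f"{condition}-{k:03d}", condition, rule, ss, **cell_kwargs)


def generate_cohort(
    n_cells: int,
    condition: str,
    rule: PlasticityRule | None = None,
    seed: int = 0,
    **cell_kwargs,
) -> list[CellSession]:
    """Materialized cohort.  Holds every sweep in memory; for large
    cohorts prefer :func:`iter_cohort` and process cells as they arrive."""
    return list(iter_cohort(n_cells, condition, rule, seed, **cell_kwargs))
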