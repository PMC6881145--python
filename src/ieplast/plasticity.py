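"""Spike-count-dependent homeostatic update of the model conductances."""

from __future__ import annotations

from .params import NeuronParams, PlasticityRule


def apply_plasticity(
    params: NeuronParams,
    rule: PlasticityRule,
    n_spikes: int,
    fraction: float = 1.0,
) -> NeuronParams:
    """Scale gD up and gh down in proportion to the evoked spike count.

    ``gD_max`` is multiplied by ``1 + min(alpha_D * n_spikes, cap_D)`` and
    ``gh_max`` by ``1 - min(alpha_h * n_spikes, cap_h)``; all other fields
    are unchanged.  ``fraction`` in [0, 1] scales the expressed change and
    models the gradual build-up of the effect after induction.
    """
    if n_spikes < 0:
        raise ValueError("n_spikes must be non-negative")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    d_up = min(rule.alpha_D * n_spikes, rule.cap_D) * fraction
    h_down = min(rule.alpha_h * n_spikes, rule.cap_h) * fraction
    return params.with_updates(
        gD_max=params.gD_max * (1.0 + d_up),
        gh_max=params.gh_max * (1.0 - h_down),
    )
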