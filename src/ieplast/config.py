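"""Pipeline configuration and run manifests.

Every analysis constant defaults to the value used in the original
in vivo protocol and analysis (step timing and amplitudes, the 10 V/s
spike criterion, the 10-ms burst ISI, the 150/50-ms measurement windows,
the quality-control bounds, the 250-spike subset criterion and the 0.1
place-cell inclusion cutoffs); overrides are recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

from .params import NeuronParams, PlasticityRule, StimulusProtocol


@dataclass
class PipelineConfig:
    seed: int = 0
    conditions: tuple[str, ...] = ("TBS", "control")
    n_cells: dict = field(default_factory=lambda: {"TBS": 16, "control": 11})
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    rule: PlasticityRule = field(default_factory=PlasticityRule)
    dt_ms: float = 0.025
    # analysis constants
    dvdt_threshold_V_s: float = 10.0
    burst_isi_ms: float = 10.0
    rin_window_ms: float = 150.0
    sag_steady_ms: float = 50.0
    ahp_window_ms: float = 50.0
    vm_segment_s: float = 5.0
    qc_vm_max_mV: float = -55.0
    qc_rs_max_mohm: float = 100.0
    qc_spike_amp_min_mV: float = 40.0
    dtx_min_spikes: int = 250
    inclusion_cutoff: float = 0.1
    post_timepoint: str = "20"
    include_spontaneous: bool = True
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, versions, output digests."""

    config: dict
    versions: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    @classmethod
    def create(cls, config: PipelineConfig) -> "RunManifest":
        import numpy, pandas, scipy

        from . import __version__

        return cls(
            config=config.to_dict(),
            versions={
                "ieplast": __version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pandas.__version__,
                "python": platform.python_version(),
            },
        )

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(Path(path).name)] = file_digest(path)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, sort_keys=True)
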