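"""Pipeline configuration: every tunable of the detection pipeline.

Defaults equal the published values; any override is recorded in the run
log together with a hash of the full configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # preprocessing
    neuropil_coeff: float = 0.7
    baseline_window: float = 30.0
    filter_cutoff: float = 1.0
    filter_order_min: int = 3
    filter_order_max: int = 5

    # EEG spike detection
    eeg_k_sd: float = 4.5
    eeg_min_separation: float = 0.7
    spectral_ratio_min: float = 20.0
    spectral_isi_min: float = 0.7
    kernel_half_width: float = 0.5
    recover_k_sd: float = 5.0
    recover_min_separation: float = 1.0

    # population events
    population_top_frac: float = 0.15
    model_spike_sigma: float = 0.33
    reconcile_tol: float = 0.2
    preictal_buffer: float = 2.0

    # per-cell recruitment
    cell_top_frac: float = 0.20
    pis_seed_tol: float = 1.5
    pis_peak_z: float = 4.0
    seizure_sigma: float = 1.0
    terminal_sigma: float = 5.0
    seizure_window: float = 10.0
    terminal_window: float = 5.0
    seizure_seed_tol: float = 3.0
    terminal_seed_tol: float = 5.0
    increase_factor: float = 1.2
    stats_margin: float = 10.0

    # evaluation
    match_tol: float = 1.0
    f1_variant: str = "geometric"
    snr_prominence_min: float = 1.0
    poisson_reps: int = 50

    # wave model
    l1_lambda: float = 0.0
    n_shuffles: int = 1000

    # misc
    t0_offset: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Load a YAML/JSON config file (optional) and apply overrides."""
    d: dict = {}
    if path is not None:
        text = Path(path).read_text()
        d = yaml.safe_load(text) or {}
    d.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig.from_dict(d)
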