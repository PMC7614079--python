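"""Pipeline configuration: every tunable default in one serialisable place.

Configs are nested dataclasses loadable from YAML; unknown keys are rejected
before any computation, and the canonical-JSON SHA-256 of a config is embedded
in every report for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "config_hash"]


def _from_dict(cls, data: dict):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        sub = _SECTION_TYPES.get((cls.__name__, name))
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _from_dict(sub, value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass
class FJCConfig:
    kuhn_length_nm: float = 1.1
    thermal_energy_pNnm: float = 4.11
    reference_Lc_nm: float = 42.5


@dataclass
class IdealizationConfig:
    k_levels: int | None = 2
    debounce_samples: int = 3
    threshold_mode: str = "means"  # or "midpoints"
    gmm_max_samples: int = 200_000
    min_dip: float = 0.001


@dataclass
class IsomerConfig:
    window_transitions: int = 10
    high_cut: float = 0.8
    low_cut: float = 0.6
    min_windows: int = 3


@dataclass
class JanssonConfig:
    grid_min_nm: float = -5.0
    grid_max_nm: float = 25.0
    bin_nm: float = 0.25
    iterations: int = 500
    relaxation: float = 1.0
    tolerance: float = 1e-6
    boundary: str = "reflect"
    density_floor: float = 1e-8
    psf_sd_nm: float = 0.85
    highpass_cutoff_hz: float = 1.0


@dataclass
class SimulatorConfig:
    scenario: str = "r3"  # "r3" (full catalog) or "two_state"
    duration_s: float = 600.0
    force_pN: float = 8.5
    sampling_rate_hz: float = 1500.0
    baseline_noise_sd_nm: float = 0.85
    drift_rate_nm_per_s: float = 0.0
    transition_path_duration_s: float = 0.0
    delta_x_total_nm: float = 0.0
    seed: int = 0
    initial_label: str | None = None


@dataclass
class StructuresConfig:
    n_residues: int = 110
    nm_per_residue: float = 0.4
    helices: list | None = None  # [[start, end], ...]; default even four-helix split
    weight_z: float = 1.0
    weight_Lc: float = 1.0


@dataclass
class PipelineConfig:
    fjc: FJCConfig = field(default_factory=FJCConfig)
    idealization: IdealizationConfig = field(default_factory=IdealizationConfig)
    isomer: IsomerConfig = field(default_factory=IsomerConfig)
    jansson: JanssonConfig = field(default_factory=JanssonConfig)
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    structures: StructuresConfig = field(default_factory=StructuresConfig)
    reference_label: str = "F"
    output_dir: str = "foldscape_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


_SECTION_TYPES = {
    ("PipelineConfig", "fjc"): FJCConfig,
    ("PipelineConfig", "idealization"): IdealizationConfig,
    ("PipelineConfig", "isomer"): IsomerConfig,
    ("PipelineConfig", "jansson"): JanssonConfig,
    ("PipelineConfig", "simulator"): SimulatorConfig,
    ("PipelineConfig", "structures"): StructuresConfig,
}


def load_config(path) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must hold a mapping")
    return PipelineConfig.from_dict(data)


def config_hash(config: PipelineConfig) -> str:
    """SHA-256 of the canonical JSON form (first 12 hex digits)."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
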