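"""Run configuration: a single validated JSON document for full runs.

A RunConfig collects everything a sweep or reproduction run needs —
wavelength presets, SDS grid, MC settings, detection-model parameters,
phantom settings, output directory, global seed — with defaults equal to
the study conditions.  Loading is strict: unknown keys and out-of-domain
values raise a ConfigError naming the offending keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .tissue_optics import TISSUE_PRESETS

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    wavelengths: tuple[str, ...] = ("488", "640", "780")
    sds_mm: tuple[float, ...] = (0.3, 1.0, 2.0, 3.0, 5.0, 6.0, 12.0)
    n_photons: int = 100_000_000
    time_gate_ns: float = 5.0
    extent_mm: float = 50.0
    voxel_size_mm: float = 0.25
    seed: int = 0
    noise_fraction: float = 0.002
    baseline_fraction: float = 0.1
    threshold_multiple: float = 5.0
    calibration_wavelength: str = "780"
    calibration_sds_mm: float = 0.3
    calibration_depth_mm: float = 3.5
    phantom_depths_mm: tuple[float, ...] = (0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
    phantom_concentration_per_ml: float = 1000.0
    phantom_flow_rate_ul_min: float = 50.0
    phantom_duration_s: float = 60.0
    sampling_rate_hz: float = 2000.0
    laser_power_mw: float = 20.0
    spot_diameter_mm: float = 3.0
    out_dir: str = "difc_out"

    def __post_init__(self):
        bad = []
        for w in self.wavelengths:
            if str(w) not in TISSUE_PRESETS:
                bad.append(
                    f"wavelengths: unknown preset {w!r} (valid: {', '.join(sorted(TISSUE_PRESETS))})"
                )
        if str(self.calibration_wavelength) not in TISSUE_PRESETS:
            bad.append(f"calibration_wavelength: unknown preset {self.calibration_wavelength!r}")
        positive = (
            "n_photons",
            "time_gate_ns",
            "extent_mm",
            "voxel_size_mm",
            "calibration_depth_mm",
            "phantom_flow_rate_ul_min",
            "phantom_duration_s",
            "sampling_rate_hz",
            "spot_diameter_mm",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                bad.append(f"{name}: must be > 0, got {getattr(self, name)}")
        for name in ("noise_fraction", "baseline_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                bad.append(f"{name}: must be in (0, 1), got {v}")
        if any(s < 0 for s in self.sds_mm):
            bad.append("sds_mm: separations must be >= 0")
        if bad:
            raise ConfigError("invalid configuration: " + "; ".join(bad))
        # normalize container types so round trips compare equal
        object.__setattr__(self, "wavelengths", tuple(str(w) for w in self.wavelengths))
        object.__setattr__(self, "sds_mm", tuple(float(s) for s in self.sds_mm))
        object.__setattr__(
            self, "phantom_depths_mm", tuple(float(d) for d in self.phantom_depths_mm)
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(
                "unknown configuration keys: "
                + ", ".join(unknown)
                + "; known keys: "
                + ", ".join(sorted(known))
            )
        return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration; defaults fill gaps."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file {path} does not exist")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ConfigError(f"{path} is not valid JSON: {e}") from e
    if not isinstance(data, dict):
        raise ConfigError(f"{path} must contain a JSON object")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the canonical configuration document."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
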