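"""Persistence: volumes as NIfTI + JSON sidecar, traces as HDF5, tables as CSV.

Every artifact carries provenance (package version, seed, configuration
hash where available) in its sidecar or attributes so runs can be traced
and reproduced bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .jacobian import SensitivityMap
from .synth import FlowPhantomConfig, Trace
from .tissue_optics import FluenceField


def _sidecar(path: Path, meta: dict) -> None:
    meta = dict(meta, package_version=__version__)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2) + "\n")


def save_volume(field: FluenceField | SensitivityMap, path: str | Path) -> Path:
    """Write a scalar voxel volume as NIfTI with a JSON metadata sidecar."""
    path = Path(path)
    if isinstance(field, SensitivityMap):
        values = field.W
        meta = {
            "kind": "sensitivity",
            "source_position_mm": list(map(float, field.source_position)),
            "detector_position_mm": list(map(float, field.detector_position)),
            "sds_mm": field.sds,
            "wavelength_nm": field.wavelength_nm,
            "n_photons": field.n_photons,
            "seed": field.seed,
        }
        volume = field.volume
        props = field.props
    else:
        values = field.values
        meta = {
            "kind": "fluence",
            "source_position_mm": list(map(float, field.source_position)),
            "geometry": field.geometry,
            "source_type": field.source_type,
            "n_photons": field.n_photons,
            "seed": field.seed,
            "escaped_weight": field.escaped_weight,
            "absorbed_weight": field.absorbed_weight,
            "inflight_weight": field.inflight_weight,
        }
        volume = field.volume
        props = field.props
    meta["voxel_size_mm"] = volume.voxel_size_mm
    meta["extent_mm"] = list(volume.extent_mm)
    meta["optical_properties"] = {
        "mu_a": props.mu_a,
        "mu_s": props.mu_s,
        "g": props.g,
        "n": props.n,
        "wavelength_nm": props.wavelength_nm,
    }
    affine = np.diag([volume.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine), str(path))
    _sidecar(path, meta)
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    img = nib.load(str(path))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return np.asarray(img.dataobj), meta


def save_trace(trace: Trace, path: str | Path) -> Path:
    """Write a two-probe trace (channels + event log + config) to HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("channels", data=trace.channels, compression="gzip")
        ev = f.create_group("events")
        for col in trace.events.columns:
            ev.create_dataset(col, data=np.asarray(trace.events[col], dtype=float))
        for k, v in vars(trace.config).items():
            f.attrs[k] = v
        f.attrs["sampling_rate_hz"] = trace.sampling_rate_hz
        f.attrs["background"] = trace.background
        f.attrs["noise_sigma"] = trace.noise_sigma
        f.attrs["full_scale"] = trace.full_scale
        f.attrs["package_version"] = __version__
    return path


def load_trace(path: str | Path) -> Trace:
    with h5py.File(path, "r") as f:
        channels = f["channels"][...]
        events = pd.DataFrame({k: f["events"][k][...] for k in f["events"]})
        attrs = dict(f.attrs)
    cfg_fields = {k: attrs[k] for k in vars(FlowPhantomConfig()) if k in attrs}
    cfg_fields["seed"] = int(cfg_fields.get("seed", 0))
    config = FlowPhantomConfig(**cfg_fields)
    return Trace(
        channels=channels,
        sampling_rate_hz=float(attrs["sampling_rate_hz"]),
        events=events,
        config=config,
        background=float(attrs["background"]),
        noise_sigma=float(attrs["noise_sigma"]),
        full_scale=float(attrs.get("full_scale", 1.0)),
    )


def save_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> Path:
    """Tidy CSV with a JSON provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    _sidecar(path, meta or {})
    return path
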