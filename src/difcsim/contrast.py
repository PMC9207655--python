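"""Peak-to-background detection-limit model and its design sweeps.

The detected fluorescence signal is linear in the fluorescence yield
distribution (first-order Born), and splits into a transient peak from a
single moving cell — a sub-voxel point of yield eta_cell at depth d on the
probe midline — plus a background from homogeneous tissue autofluorescence
of yield eta_af per voxel:

    peak(d)    = eta_cell * W(midline, d)
    background = eta_af   * sum_j W_j

The background itself is subtracted in processing; what limits detection is
the additive instrument noise, modeled as Gaussian with sigma equal to a
fixed fraction (0.2%) of the background level.  A peak is detectable when
it exceeds ``threshold_multiple`` (5) times that noise, i.e. an SNR of
20*log10(5) = 13.9 dB.  Because the PMT gain scales peak and background
together, every detectability statement reduces to the gain-free ratio
W(midline, d) / sum(W) times eta_cell / eta_af.

The single-cell yield eta_cell was never published; it is fixed by a
calibration anchor — the NIR flow-phantom result that a microsphere at
3.5 mm depth is just detectable at 0.3-mm SDS — and the model then
predicts detection depths for every other wavelength/SDS combination,
including their sensitivity to +-50% errors in optical properties and in
cell brightness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    GeometryError,
    SingularInputError,
    UndefinedRatioError,
)
from .jacobian import (
    SensitivityMap,
    midline_column,
    probe_positions,
    sensitivity_map,
)
from .tissue_optics import MCConfig, VoxelVolume, get_preset, simulate_fluence
from .jacobian import born_sensitivity

__all__ = [
    "DetectionModel",
    "ContrastCurve",
    "peak_signal",
    "background_signal",
    "snr_db",
    "contrast_curve",
    "max_detection_depth",
    "calibrate_eta_cell",
    "sds_argmax_at_depth",
    "sds_best_median",
    "extended_source_curve",
    "hex_disk_points",
    "irradiance_check",
    "property_perturbation_sweep",
    "brightness_perturbation_sweep",
]

#: Default IEC skin-exposure limit in the NIR, mW/cm^2.
IEC_LIMIT_MW_PER_CM2 = 300.0


@dataclass(frozen=True)
class DetectionModel:
    """Detection-limit parameters (yields, noise, threshold)."""

    eta_cell: float = 1.0
    eta_af: float = 1.0
    noise_fraction: float = 0.002
    baseline_fraction: float = 0.1
    threshold_multiple: float = 5.0

    def __post_init__(self):
        if self.eta_cell < 0 or self.eta_af < 0:
            raise ValueError("yields must be >= 0")
        if not 0 < self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in (0, 1)")
        if not 0 < self.baseline_fraction < 1:
            raise ValueError("baseline_fraction must be in (0, 1)")
        if self.threshold_multiple <= 0:
            raise ValueError("threshold_multiple must be > 0")

    @property
    def snr_floor_db(self) -> float:
        """Minimum detectable peak-to-noise ratio, dB: 20 log10(threshold)."""
        return 20.0 * math.log10(self.threshold_multiple)

    def replace(self, **kw) -> "DetectionModel":
        return replace(self, **kw)


@dataclass
class ContrastCurve:
    """Modeled peak-to-noise ratio (dB) versus cell depth."""

    depths: np.ndarray
    snr_db: np.ndarray
    wavelength_nm: float | None = None
    sds_mm: float | None = None
    spot_diameter_mm: float | None = None


def _depth_index(smap: SensitivityMap, depth_mm: float) -> int:
    dxv = smap.volume.voxel_size_mm
    nz = smap.W.shape[2]
    if not 0 <= depth_mm < nz * dxv:
        raise GeometryError(f"depth {depth_mm} mm outside the volume")
    return int(math.floor(depth_mm / dxv))


def peak_signal(smap: SensitivityMap, depth_mm: float, model: DetectionModel) -> float:
    """Transient peak from a single cell at the given midline depth.

    The cell occupies the voxel containing ``depth_mm`` on the vertical
    column under the source-detector midpoint.
    """
    col = midline_column(smap)
    return float(model.eta_cell * col[_depth_index(smap, depth_mm)])


def background_signal(smap: SensitivityMap, model: DetectionModel) -> float:
    """Autofluorescence background: eta_af times the whole-volume sum of W."""
    return float(model.eta_af * smap.total)


def snr_db(peak: float, model: DetectionModel, background: float) -> float:
    """Peak-to-noise ratio in dB with noise = noise_fraction * background.

    Independent of any common gain applied to peak and background (the PMT
    gain is raised with SDS to keep the background level matched, so gain
    cancels).
    """
    if background <= 0:
        raise UndefinedRatioError("background must be > 0")
    noise = model.noise_fraction * background
    if peak <= 0:
        return float("-inf")
    return 20.0 * math.log10(peak / noise)


def contrast_curve(
    smap: SensitivityMap, model: DetectionModel, max_depth_mm: float = 8.0
) -> ContrastCurve:
    """Peak-to-noise curve over midline depths up to ``max_depth_mm``."""
    col = midline_column(smap)
    depths = smap.volume.depth_centers(max_depth_mm)
    bg = background_signal(smap, model)
    if bg <= 0:
        raise UndefinedRatioError("background must be > 0")
    noise = model.noise_fraction * bg
    vals = model.eta_cell * col[: len(depths)]
    with np.errstate(divide="ignore"):
        snr = 20.0 * np.log10(np.where(vals > 0, vals / noise, np.nan))
    snr = np.where(np.isnan(snr), -np.inf, snr)
    return ContrastCurve(
        depths=depths,
        snr_db=snr,
        wavelength_nm=smap.wavelength_nm,
        sds_mm=smap.sds,
    )


def max_detection_depth(curve: ContrastCurve, model: DetectionModel) -> float | None:
    """Deepest voxel-center depth whose modeled SNR clears the floor.

    Returns None when no depth qualifies.
    """
    ok = curve.snr_db >= model.snr_floor_db - 1e-12
    if not ok.any():
        return None
    return float(curve.depths[np.nonzero(ok)[0][-1]])


def calibrate_eta_cell(
    smap: SensitivityMap,
    model: DetectionModel,
    target_depth_mm: float,
    max_depth_mm: float = 8.0,
    rel_tol: float = 1e-3,
) -> DetectionModel:
    """Smallest eta_cell whose detection depth equals the target.

    The target is mapped to the nearest voxel center (ties toward the
    shallower one), the model's depth resolution.  Snapping to the
    half-open containing voxel instead would bias a boundary target like
    3.5 mm a half voxel deep and — because calibration pins the anchor
    voxel exactly onto the detection floor — would leave the model's
    working point degenerate, with downstream quantized depths flipping a
    full voxel under Monte Carlo noise.  Bisection on eta_cell to 0.1%
    relative; raises CalibrationError when the target cannot be realized
    (e.g. the profile does not decay through it).
    """
    dxv = smap.volume.voxel_size_mm
    k = math.floor(target_depth_mm / dxv - 0.5 + 1e-12)
    c_lo = (k + 0.5) * dxv
    c_hi = (k + 1.5) * dxv
    target_center = c_lo if target_depth_mm - c_lo <= c_hi - target_depth_mm else c_hi
    if target_center >= max_depth_mm:
        raise CalibrationError("target depth beyond the evaluated curve support")

    def depth_for(eta: float) -> float | None:
        c = contrast_curve(smap, model.replace(eta_cell=eta), max_depth_mm)
        return max_detection_depth(c, model)

    lo, hi = 1e-12, 1e12
    # bracket: find hi with depth >= target and lo with depth < target
    if (d := depth_for(hi)) is None or d < target_center:
        raise CalibrationError(
            f"target depth {target_depth_mm} mm unreachable for this map"
        )
    if (d := depth_for(lo)) is not None and d >= target_center:
        raise CalibrationError("target depth shallower than the first voxel")
    while hi / lo > 1 + rel_tol:
        mid = math.sqrt(lo * hi)
        d = depth_for(mid)
        if d is not None and d >= target_center:
            hi = mid
        else:
            lo = mid
    achieved = depth_for(hi)
    if achieved is None or abs(achieved - target_center) > dxv / 2:
        raise CalibrationError(
            f"calibration overshoots: achieved {achieved} mm for target {target_center} mm"
        )
    return model.replace(eta_cell=hi)


def _snr_at_depth(curve: ContrastCurve, depth_mm: float, voxel: float) -> float:
    # value of the voxel containing the depth: center c with c - v/2 <= d < c + v/2
    diffs = depth_mm - np.asarray(curve.depths)
    inside = (diffs >= -voxel / 2 - 1e-9) & (diffs < voxel / 2 - 1e-9)
    if not inside.any():
        raise GeometryError(f"depth {depth_mm} mm outside curve support")
    return float(curve.snr_db[np.nonzero(inside)[0][0]])


def sds_argmax_at_depth(curves: dict[float, ContrastCurve], depth_mm: float, voxel_mm: float = 0.25) -> float:
    """SDS whose curve is highest at the given depth; ties go to smaller SDS."""
    if len(curves) < 2:
        raise ValueError("need at least two curves")
    best_sds, best_val = None, -np.inf
    for s in sorted(curves):
        v = _snr_at_depth(curves[s], depth_mm, voxel_mm)
        if v > best_val:
            best_sds, best_val = s, v
    return float(best_sds)


def sds_best_median(
    curves: dict[float, ContrastCurve],
    depth_range_mm: tuple[float, float] = (2.0, 4.0),
    step_mm: float = 0.25,
    voxel_mm: float = 0.25,
) -> float:
    """SDS with the best median SNR over a depth range (default 2-4 mm)."""
    lo, hi = depth_range_mm
    depths = np.arange(lo, hi + step_mm / 2, step_mm)
    best_sds, best_val = None, -np.inf
    for s in sorted(curves):
        med = float(np.median([_snr_at_depth(curves[s], d, voxel_mm) for d in depths]))
        if med > best_val:
            best_sds, best_val = s, med
    return float(best_sds)


def hex_disk_points(center_xy, diameter_mm: float, n_rings: int = 3) -> np.ndarray:
    """Hexagonally packed points covering a disk (37 points for 3 rings)."""
    if diameter_mm <= 0:
        raise SingularInputError("diameter must be > 0")
    radius = diameter_mm / 2.0
    pitch = radius / n_rings
    pts = []
    for i in range(-2 * n_rings, 2 * n_rings + 1):
        for j in range(-2 * n_rings, 2 * n_rings + 1):
            x = pitch * (i + 0.5 * j)
            y = pitch * (math.sqrt(3) / 2.0) * j
            if x * x + y * y <= radius * radius + 1e-12:
                pts.append((center_xy[0] + x, center_xy[1] + y))
    return np.asarray(pts, dtype=float)


def extended_source_curve(
    volume: VoxelVolume,
    props,
    sds_mm: float,
    spot_diameter_mm: float,
    config: MCConfig,
    model: DetectionModel,
    max_depth_mm: float = 8.0,
) -> ContrastCurve:
    """Contrast curve with the excitation spread over a finite spot.

    The excitation Green's function is the equal-weight average of pencil
    beams on a hexagonal grid (>= 37 points) covering the disk of the given
    diameter centered on the source fiber position — one MC run with the
    launch point cycled round-robin over the grid.  Emission is collected
    at the (point) detector as usual.  Used for the IEC skin-exposure
    variant where the same laser power is spread over a 3-mm spot.
    """
    props = get_preset(props)
    rs, rd = probe_positions(volume, sds_mm)
    pts_xy = hex_disk_points(rs[:2], spot_diameter_mm)
    for x, y in pts_xy:
        if not (0 <= x <= volume.extent_mm[0] and 0 <= y <= volume.extent_mm[1]):
            raise GeometryError("illumination spot extends beyond the tissue face")
    pts = np.column_stack([pts_xy, np.zeros(len(pts_xy))])
    # equal weights: round the photon budget up to a multiple of the point count
    npts = len(pts)
    n_phot = int(math.ceil(config.n_photons / npts) * npts)
    g_ex = simulate_fluence(volume, props, pts, config.replace(n_photons=n_phot))
    g_em = simulate_fluence(
        volume, props, rd, config.replace(seed=(config.seed * 31 + 7) % 2**31)
    )
    smap = born_sensitivity(g_ex, g_em)
    # midline of the nominal fiber pair, not of the spot centroid
    smap.source_position = rs
    smap.detector_position = rd
    curve = contrast_curve(smap, model, max_depth_mm)
    curve.spot_diameter_mm = float(spot_diameter_mm)
    return curve


def irradiance_check(
    power_mw: float, spot_diameter_mm: float, limit_mw_per_cm2: float = IEC_LIMIT_MW_PER_CM2
) -> tuple[float, bool]:
    """Irradiance of a uniform spot and compliance with the IEC skin limit."""
    if power_mw < 0:
        raise ValueError("power must be >= 0")
    if spot_diameter_mm <= 0:
        raise SingularInputError("spot diameter must be > 0")
    area_cm2 = math.pi * (spot_diameter_mm / 20.0) ** 2
    irr = power_mw / area_cm2
    return irr, irr <= limit_mw_per_cm2


def property_perturbation_sweep(
    base_props,
    model: DetectionModel,
    sds_list=(0.3, 3.0),
    factors=(0.5, 1.0, 1.5),
    volume: VoxelVolume | None = None,
    config: MCConfig | None = None,
    baseline_maps: dict[float, SensitivityMap] | None = None,
    max_depth_mm: float = 8.0,
    combinations=None,
    mirror: bool = True,
) -> pd.DataFrame:
    """Detection-depth robustness to mu_a/mu_s errors.

    The detection model (calibrated at baseline) is held fixed while the
    Green's functions are rebuilt with mu_a and mu_s independently scaled;
    the table reports the modeled maximum detection depth for every
    (factor_mu_a, factor_mu_s, SDS) and its change from baseline.
    """
    base_props = get_preset(base_props)
    volume = volume or VoxelVolume()
    config = config or MCConfig()
    if combinations is None:
        combinations = [c for c in product(factors, factors)]
    baseline_maps = dict(baseline_maps or {})
    rows = []
    baseline_depth: dict[float, float | None] = {}
    for s in sds_list:
        if s not in baseline_maps:
            baseline_maps[s] = sensitivity_map(base_props, s, volume, config, mirror=mirror)
        d0 = max_detection_depth(contrast_curve(baseline_maps[s], model, max_depth_mm), model)
        baseline_depth[s] = d0
    for fa, fs in combinations:
        for s in sds_list:
            if fa == 1.0 and fs == 1.0:
                smap = baseline_maps[s]
            else:
                props = base_props.scaled(fa, fs)
                smap = sensitivity_map(props, s, volume, config, mirror=mirror)
            d = max_detection_depth(contrast_curve(smap, model, max_depth_mm), model)
            d0 = baseline_depth[s]
            delta = (d - d0) if (d is not None and d0 is not None) else np.nan
            rows.append(
                dict(
                    factor_mu_a=fa,
                    factor_mu_s=fs,
                    sds_mm=s,
                    max_depth_mm=d,
                    baseline_depth_mm=d0,
                    delta_mm=delta,
                )
            )
    return pd.DataFrame(rows)


def brightness_perturbation_sweep(
    model: DetectionModel,
    curves: dict[float, ContrastCurve],
    factors=(0.5, 1.0, 1.5),
) -> pd.DataFrame:
    """Detection-depth robustness to +-50% cell brightness.

    Scaling eta_cell by f shifts every curve by 20 log10(f) dB (Born
    linearity), so no MC reruns are needed.
    """
    rows = []
    for s, curve in sorted(curves.items()):
        d0 = max_detection_depth(curve, model)
        for f in factors:
            shifted = ContrastCurve(
                depths=curve.depths,
                snr_db=curve.snr_db + 20.0 * math.log10(f),
                wavelength_nm=curve.wavelength_nm,
                sds_mm=curve.sds_mm,
            )
            d = max_detection_depth(shifted, model)
            delta = (d - d0) if (d is not None and d0 is not None) else np.nan
            rows.append(
                dict(
                    factor_eta_cell=f,
                    sds_mm=s,
                    max_depth_mm=d,
                    baseline_depth_mm=d0,
                    delta_mm=delta,
                )
            )
    return pd.DataFrame(rows)
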