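"""Adjoint Born-approximation fluorescence sensitivity maps.

For a source at rs and detector at rd on the tissue surface, the
sensitivity of the detected fluorescence signal to a unit fluorescence
yield perturbation in voxel j is the product of two Green's functions,

    W(r_j; rs, rd) = G_ex(r_j, rs) * G_em(rd, r_j) * dV,

where the emission Green's function to every voxel is obtained with a
single additional forward run launched from the detector position
(reciprocity).  Excitation and emission share one optical-property set per
wavelength; the red shift between them is negligible against the
uncertainty of the literature properties.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import GeometryError, IncompatibleGridError, UndefinedMaximumError
from .tissue_optics import (
    FluenceField,
    MCConfig,
    OpticalProperties,
    VoxelVolume,
    get_preset,
    simulate_fluence,
)

__all__ = [
    "SensitivityMap",
    "DepthProfile",
    "born_sensitivity",
    "midline_depth_profile",
    "midline_column",
    "depth_of_max_sensitivity",
    "normalize_profiles",
    "probe_positions",
    "sds_sweep",
    "sensitivity_map",
]

#: SDS grid covering every separation named in the study (mm).
DEFAULT_SDS_MM = (0.3, 1.0, 2.0, 3.0, 5.0, 6.0, 12.0)


@dataclass
class SensitivityMap:
    """Born sensitivity W on the voxel grid for one source-detector pair.

    ``W`` carries the product-of-Green's-functions units (mm^-4 per
    launched-photon pair) times the voxel volume dV (mm^3); all reported
    ratios are invariant to this overall scale.
    """

    W: np.ndarray
    volume: VoxelVolume
    props: OpticalProperties
    source_position: np.ndarray
    detector_position: np.ndarray
    n_photons: int = 0
    seed: int | None = None

    @property
    def sds(self) -> float:
        return float(np.linalg.norm(self.source_position - self.detector_position))

    @property
    def wavelength_nm(self) -> float | None:
        return self.props.wavelength_nm

    @property
    def total(self) -> float:
        """Whole-volume sum of W (the homogeneous-background integral)."""
        return float(self.W.sum())


@dataclass
class DepthProfile:
    """Sensitivity along the vertical column under the probe midpoint."""

    depths: np.ndarray
    values: np.ndarray
    normalization: str = "raw"
    wavelength_nm: float | None = None
    sds_mm: float | None = None

    def normalized_to_own_max(self) -> "DepthProfile":
        m = self.values.max()
        if m <= 0:
            raise UndefinedMaximumError("all-zero profile has no maximum")
        return replace(self, values=self.values / m, normalization="normalized-to-own-max")


def born_sensitivity(g_ex: FluenceField, g_em_adjoint: FluenceField) -> SensitivityMap:
    """Assemble W from an excitation field and a detector-launched field.

    Both fields must share the voxel grid and the optical-property set;
    ``g_em_adjoint`` must have been launched from the detector position
    (the reciprocity trick: G_em(rd, r_j) = G_em(r_j, rd)).
    """
    if g_ex.values.shape != g_em_adjoint.values.shape:
        raise IncompatibleGridError(
            f"grid mismatch: {g_ex.values.shape} vs {g_em_adjoint.values.shape}"
        )
    if g_ex.volume.voxel_size_mm != g_em_adjoint.volume.voxel_size_mm:
        raise IncompatibleGridError("voxel size mismatch between Green's functions")
    pa, pb = g_ex.props, g_em_adjoint.props
    if (pa.mu_a, pa.mu_s, pa.g, pa.n) != (pb.mu_a, pb.mu_s, pb.g, pb.n):
        raise IncompatibleGridError("optical-property mismatch between Green's functions")
    dV = g_ex.volume.voxel_size_mm**3
    W = g_ex.values * g_em_adjoint.values * dV
    return SensitivityMap(
        W=W,
        volume=g_ex.volume,
        props=pa,
        source_position=np.asarray(g_ex.source_position, dtype=float),
        detector_position=np.asarray(g_em_adjoint.source_position, dtype=float),
        n_photons=g_ex.n_photons,
        seed=g_ex.seed,
    )


def _columns_for(coordinate: float, voxel: float, n: int) -> list[int]:
    """Voxel column indices for a surface coordinate.

    When the coordinate falls on a voxel boundary the two adjacent columns
    are both returned (they are averaged), avoiding a half-voxel bias.
    """
    t = coordinate / voxel
    nearest = round(t)
    if abs(t - nearest) < 1e-9:  # on a boundary
        cols = [nearest - 1, nearest]
        cols = [c for c in cols if 0 <= c < n]
        if not cols:
            raise GeometryError(f"coordinate {coordinate} mm falls outside the grid")
        return cols
    c = int(np.floor(t))
    if not 0 <= c < n:
        raise GeometryError(f"coordinate {coordinate} mm falls outside the grid")
    return [c]


def midline_column(smap: SensitivityMap) -> np.ndarray:
    """Full-depth W column through the source-detector midpoint."""
    mid = 0.5 * (smap.source_position + smap.detector_position)
    nx, ny, nz = smap.W.shape
    dxv = smap.volume.voxel_size_mm
    cols_x = _columns_for(float(mid[0]), dxv, nx)
    cols_y = _columns_for(float(mid[1]), dxv, ny)
    block = smap.W[np.ix_(cols_x, cols_y, range(nz))]
    return block.mean(axis=(0, 1))


def midline_depth_profile(smap: SensitivityMap, max_depth_mm: float = 5.0) -> DepthProfile:
    """Depth profile of W under the probe midpoint (default 0-5 mm)."""
    for p in (smap.source_position, smap.detector_position):
        if abs(p[2]) > 1e-9:
            raise GeometryError("source and detector must lie on the z=0 face")
    col = midline_column(smap)
    depths = smap.volume.depth_centers(max_depth_mm)
    return DepthProfile(
        depths=depths,
        values=col[: len(depths)].copy(),
        normalization="raw",
        wavelength_nm=smap.wavelength_nm,
        sds_mm=smap.sds,
    )


def depth_of_max_sensitivity(profile: DepthProfile) -> float:
    """Voxel-center depth of the profile maximum; ties go to the shallowest."""
    if profile.values.size == 0 or profile.values.max() <= 0:
        raise UndefinedMaximumError("profile is empty or all zero")
    return float(profile.depths[int(np.argmax(profile.values))])


def normalize_profiles(profiles: list[DepthProfile]) -> list[DepthProfile]:
    """Normalize a collection by its single global maximum.

    Every value is divided by the one largest value across all profiles, so
    exactly one sample equals 1 afterward and cross-profile comparisons
    (wavelength x SDS) stay meaningful.
    """
    if not profiles:
        raise UndefinedMaximumError("empty profile collection")
    for p in profiles:
        if p.normalization != "raw":
            raise UndefinedMaximumError("profiles must be raw before global normalization")
    gmax = max(float(p.values.max()) for p in profiles)
    if gmax <= 0:
        raise UndefinedMaximumError("all profiles are zero")
    return [
        replace(p, values=p.values / gmax, normalization="normalized-to-global-max")
        for p in profiles
    ]


def probe_positions(volume: VoxelVolume, sds_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Source/detector surface points: top-face center +- sds/2 along x."""
    if sds_mm < 0:
        raise GeometryError("SDS must be >= 0")
    cx, cy, _ = volume.top_face_center
    half = sds_mm / 2.0
    if half > cx or half > volume.extent_mm[0] - cx:
        raise GeometryError(f"SDS {sds_mm} mm does not fit on the {volume.extent_mm[0]} mm face")
    rs = np.array([cx - half, cy, 0.0])
    rd = np.array([cx + half, cy, 0.0])
    return rs, rd


def _derived_seed(base_seed: int, *tokens) -> int:
    import zlib

    label = "|".join(str(t) for t in tokens)
    return (int(base_seed) * 2654435761 + zlib.crc32(label.encode())) % (2**31)


def sensitivity_map(
    props: OpticalProperties | str,
    sds_mm: float,
    volume: VoxelVolume | None = None,
    config: MCConfig | None = None,
    mirror: bool = True,
    green_cache: dict | None = None,
) -> SensitivityMap:
    """Run the MC pair (or its mirror shortcut) and assemble W for one SDS.

    With ``mirror=True`` the detector-launched Green's function is taken as
    the exact x-reflection of the source-launched one (the homogeneous box
    and the centered pair are mirror-symmetric, so the flipped tally is
    statistically equivalent to an independent run).  This halves the MC
    cost of sweeps; set ``mirror=False`` to compute both fields
    independently.
    """
    props = get_preset(props)
    volume = volume or VoxelVolume()
    config = config or MCConfig()
    rs, rd = probe_positions(volume, sds_mm)

    def _field(position, role):
        seed = _derived_seed(config.seed, props.wavelength_nm, sds_mm, role)
        key = (tuple(position), props.mu_a, props.mu_s, config.n_photons, seed)
        if green_cache is not None and key in green_cache:
            return green_cache[key]
        f = simulate_fluence(volume, props, position, config.replace(seed=seed))
        if green_cache is not None:
            green_cache[key] = f
        return f

    g_ex = _field(rs, "src")
    if mirror:
        g_em = g_ex.mirrored_x()
    else:
        g_em = _field(rd, "det")
    return born_sensitivity(g_ex, g_em)


def sds_sweep(
    props: OpticalProperties | str,
    sds_list=DEFAULT_SDS_MM,
    volume: VoxelVolume | None = None,
    config: MCConfig | None = None,
    mirror: bool = True,
) -> dict[float, SensitivityMap]:
    """Sensitivity maps for a set of separations at one wavelength.

    Green's functions are cached by launch position so repeated positions
    across the sweep are not recomputed.
    """
    if not len(sds_list):
        raise GeometryError("sds_list must be non-empty")
    cache: dict = {}
    out = {}
    for s in sds_list:
        out[float(s)] = sensitivity_map(
            props, float(s), volume=volume, config=config, mirror=mirror, green_cache=cache
        )
    return out
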