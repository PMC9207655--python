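"""Voxelized Monte Carlo photon transport in homogeneous tissue.

The simulated medium is a homogeneous cube (default 50 mm side, 0.25-mm
voxels) with the illuminated surface at z=0 and z increasing into the
tissue.  Transport follows the standard weighted-packet scheme: exponential
scattering steps of mean 1/mu_s, continuous absorption weighting
exp(-mu_a*l) along each step, Henyey-Greenstein deflection with anisotropy
g at every scattering event, Fresnel reflection/transmission at the top
surface (tissue index n against air), termination at the other five faces,
a time gate on total photon time of flight, and Russian roulette on
low-weight packets.

Closed-form diffusion-theory fluence (infinite medium and semi-infinite
extrapolated-boundary) is provided as an independent oracle for validating
the Monte Carlo estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import GeometryError, InvalidParameterError, SingularInputError

__all__ = [
    "OpticalProperties",
    "TISSUE_PRESETS",
    "get_preset",
    "VoxelVolume",
    "MCConfig",
    "FluenceField",
    "hg_sample",
    "fresnel_reflectance",
    "simulate_fluence",
    "analytic_fluence",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous-tissue optical properties at one nominal wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.
    mu_s : float
        Scattering coefficient, mm^-1.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering angle).
    n : float
        Refractive index of the medium.
    wavelength_nm : float or None
        Nominal wavelength label; carried as metadata only.
    """

    mu_a: float
    mu_s: float
    g: float = 0.9
    n: float = 1.37
    wavelength_nm: float | None = None

    def __post_init__(self):
        if self.mu_a < 0:
            raise InvalidParameterError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s <= 0:
            raise InvalidParameterError(f"mu_s must be > 0, got {self.mu_s}")
        if not -1 < self.g < 1:
            raise InvalidParameterError(f"g must be in (-1, 1), got {self.g}")
        if self.n < 1:
            raise InvalidParameterError(f"n must be >= 1, got {self.n}")

    @property
    def mu_s_reduced(self) -> float:
        """Reduced scattering coefficient mu_s' = mu_s * (1 - g), mm^-1."""
        return self.mu_s * (1.0 - self.g)

    @property
    def diffusion_coefficient(self) -> float:
        """Diffusion coefficient D = 1 / (3 (mu_a + mu_s')), mm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_reduced))

    @property
    def mu_eff(self) -> float:
        """Effective attenuation sqrt(3 mu_a (mu_a + mu_s')), mm^-1."""
        return math.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_reduced))

    @property
    def transport_mfp(self) -> float:
        """Transport mean free path 1/mu_s', mm."""
        return 1.0 / self.mu_s_reduced

    def scaled(self, factor_mu_a: float = 1.0, factor_mu_s: float = 1.0) -> "OpticalProperties":
        """Return a copy with mu_a and mu_s multiplied by the given factors."""
        return OpticalProperties(
            mu_a=self.mu_a * factor_mu_a,
            mu_s=self.mu_s * factor_mu_s,
            g=self.g,
            n=self.n,
            wavelength_nm=self.wavelength_nm,
        )


#: Literature optical properties of human arm tissue at the three DiFC
#: laser lines (blue-green, red, NIR).
TISSUE_PRESETS: dict[str, OpticalProperties] = {
    "488": OpticalProperties(mu_a=0.05, mu_s=25.0, g=0.9, n=1.37, wavelength_nm=488.0),
    "640": OpticalProperties(mu_a=0.025, mu_s=10.0, g=0.9, n=1.37, wavelength_nm=640.0),
    "780": OpticalProperties(mu_a=0.002, mu_s=7.0, g=0.9, n=1.37, wavelength_nm=780.0),
}


def get_preset(name: str | OpticalProperties) -> OpticalProperties:
    """Resolve a wavelength preset by label ("488", "640", "780")."""
    if isinstance(name, OpticalProperties):
        return name
    key = str(name)
    if key not in TISSUE_PRESETS:
        raise InvalidParameterError(
            f"unknown wavelength preset {name!r}; valid presets: "
            + ", ".join(sorted(TISSUE_PRESETS))
        )
    return TISSUE_PRESETS[key]


@dataclass(frozen=True)
class VoxelVolume:
    """Cubic (or box) voxel grid; z=0 is the illuminated surface.

    Axes: x along the source-detector line, y along the vessel/flow
    direction, z depth into tissue.  Voxel i spans [i*dx, (i+1)*dx) and
    positions are in mm from the corner of the box.
    """

    extent_mm: tuple[float, float, float] = (50.0, 50.0, 50.0)
    voxel_size_mm: float = 0.25

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise InvalidParameterError("voxel_size_mm must be > 0")
        for e in self.extent_mm:
            ratio = e / self.voxel_size_mm
            if abs(ratio - round(ratio)) > 1e-6:
                raise InvalidParameterError(
                    f"extent {e} mm is not divisible by voxel size {self.voxel_size_mm} mm"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(e / self.voxel_size_mm)) for e in self.extent_mm)

    @property
    def top_face_center(self) -> np.ndarray:
        return np.array([self.extent_mm[0] / 2.0, self.extent_mm[1] / 2.0, 0.0])

    def depth_centers(self, max_depth_mm: float | None = None) -> np.ndarray:
        """Voxel-center depths, optionally limited to max_depth_mm."""
        nz = self.shape[2]
        if max_depth_mm is not None:
            nz = min(nz, int(round(max_depth_mm / self.voxel_size_mm)))
        return (np.arange(nz) + 0.5) * self.voxel_size_mm

    def contains_surface_point(self, p) -> bool:
        x, y, z = p
        return (
            abs(z) < 1e-9
            and 0.0 <= x <= self.extent_mm[0]
            and 0.0 <= y <= self.extent_mm[1]
        )


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run settings.

    Defaults mirror the reference simulation protocol (1e8 packets, 5-ns
    time gate, roulette at 1e-4 weight with 10% survival); tests and
    desk-scale sweeps pass smaller photon budgets.
    """

    n_photons: int = 100_000_000
    time_gate_ns: float = 5.0
    seed: int = 0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1

    def __post_init__(self):
        if self.n_photons < 1:
            raise InvalidParameterError("n_photons must be >= 1")
        if self.time_gate_ns <= 0:
            raise InvalidParameterError("time_gate_ns must be > 0")
        if not 0 < self.roulette_survival <= 1:
            raise InvalidParameterError("roulette_survival must be in (0, 1]")

    def replace(self, **kw) -> "MCConfig":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass
class FluenceField:
    """Voxel fluence per launched photon (mm^-2) plus packet-weight tallies."""

    values: np.ndarray
    volume: VoxelVolume
    props: OpticalProperties
    source_position: np.ndarray
    escaped_weight: float
    absorbed_weight: float
    inflight_weight: float
    n_photons: int
    n_scatter_events: int
    seed: int
    geometry: str = "semi-infinite"
    source_type: str = "pencil"
    source_points: np.ndarray | None = None

    @property
    def launched_weight(self) -> float:
        return float(self.n_photons)

    @property
    def conservation_error(self) -> float:
        """Relative imbalance of absorbed + escaped + in-flight vs launched."""
        total = self.absorbed_weight + self.escaped_weight + self.inflight_weight
        return abs(total - self.launched_weight) / self.launched_weight

    @property
    def mean_scatter_events(self) -> float:
        return self.n_scatter_events / self.n_photons

    def mirrored_x(self) -> "FluenceField":
        """The exact x-reflection of this field about the volume midplane.

        Valid because the homogeneous box and boundary conditions are
        symmetric under x -> Lx - x; the flipped tally is statistically
        equivalent to an independent run launched from the mirrored source.
        """
        src = self.source_position.copy()
        src[0] = self.volume.extent_mm[0] - src[0]
        out = FluenceField(
            values=self.values[::-1, :, :],
            volume=self.volume,
            props=self.props,
            source_position=src,
            escaped_weight=self.escaped_weight,
            absorbed_weight=self.absorbed_weight,
            inflight_weight=self.inflight_weight,
            n_photons=self.n_photons,
            n_scatter_events=self.n_scatter_events,
            seed=self.seed,
            geometry=self.geometry,
            source_type=self.source_type,
        )
        return out


def hg_sample(g: float, u) -> tuple[np.ndarray, np.ndarray]:
    """Sample Henyey-Greenstein deflection angles from uniform variates.

    Parameters
    ----------
    g : float
        Anisotropy, |g| < 1.
    u : array-like, shape (..., 2)
        Uniform [0, 1) variates; u[..., 0] drives the polar cosine,
        u[..., 1] the azimuth.

    Returns
    -------
    cos_theta, phi : ndarrays
        Polar cosine from the HG density and azimuth uniform on [0, 2pi).
    """
    if not -1 < g < 1:
        raise InvalidParameterError(f"g must be in (-1, 1), got {g}")
    u = np.asarray(u, dtype=float)
    if u.shape[-1] != 2:
        raise InvalidParameterError("u must have a trailing axis of size 2")
    u1 = u[..., 0]
    u2 = u[..., 1]
    if g == 0.0:
        cos_theta = 2.0 * u1 - 1.0
    else:
        f = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
        cos_theta = np.clip((1.0 + g * g - f * f) / (2.0 * g), -1.0, 1.0)
    phi = 2.0 * np.pi * u2
    return cos_theta, phi


def hg_cdf(g: float, cos_theta) -> np.ndarray:
    """Closed-form CDF of the HG polar cosine (oracle for sampling tests)."""
    c = np.asarray(cos_theta, dtype=float)
    if g == 0.0:
        return (c + 1.0) / 2.0
    # integral of the HG density from -1 to c
    return ((1.0 - g * g) / (2.0 * g)) * (
        1.0 / np.sqrt(1.0 + g * g - 2.0 * g * c) - 1.0 / (1.0 + g)
    )


def fresnel_reflectance(n_in: float, n_out: float, cos_incident: float) -> float:
    """Unpolarized Fresnel reflectance at a planar interface.

    Returns 1.0 beyond the critical angle.  ``cos_incident`` is the
    direction cosine against the surface normal, in (0, 1].
    """
    if n_in < 1 or n_out < 1:
        raise InvalidParameterError("refractive indices must be >= 1")
    if not 0 < cos_incident <= 1:
        raise InvalidParameterError(
            f"cos_incident must be in (0, 1], got {cos_incident}"
        )
    return _kernels.fresnel_unpolarized(float(n_in), float(n_out), float(cos_incident))


def _as_source_points(source, volume: VoxelVolume, geometry: str, source_type: str) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(source, dtype=float))
    if pts.shape[1] != 3:
        raise GeometryError("source must be a 3-vector or (k, 3) array")
    if source_type == "pencil" and geometry == "semi-infinite":
        for p in pts:
            if not volume.contains_surface_point(p):
                raise GeometryError(
                    f"pencil source {tuple(p)} must lie on the z=0 face of the volume"
                )
    return pts


def simulate_fluence(
    volume: VoxelVolume,
    props: OpticalProperties | str,
    source,
    config: MCConfig,
    geometry: str = "semi-infinite",
    source_type: str = "pencil",
    n_outside: float = 1.0,
) -> FluenceField:
    """Monte Carlo fluence Green's function for one source.

    Parameters
    ----------
    volume, props, config
        Grid, optical properties (or preset label) and MC settings.
    source
        Surface point (pencil) or interior point (isotropic), mm.  A
        (k, 3) array distributes photons round-robin over k launch points
        with equal weights (used for extended illumination spots).
    geometry
        "semi-infinite": Fresnel top face, absorbing side/bottom faces.
        "infinite": no boundaries; photons may leave and re-enter the grid,
        tallies accumulate only inside (validation mode).
    source_type
        "pencil" (+z directed) or "isotropic".

    Returns
    -------
    FluenceField
        Fluence per launched photon (mm^-2), deterministic for a given
        seed and configuration.
    """
    props = get_preset(props)
    if geometry not in ("semi-infinite", "infinite"):
        raise InvalidParameterError(f"unknown geometry {geometry!r}")
    if source_type not in ("pencil", "isotropic"):
        raise InvalidParameterError(f"unknown source_type {source_type!r}")
    pts = _as_source_points(source, volume, geometry, source_type)
    shape = volume.shape
    flu = np.zeros(shape, dtype=np.float64)
    geom_code = _kernels.GEOM_SLAB if geometry == "semi-infinite" else _kernels.GEOM_INFINITE
    absorbed, escaped, inflight, n_scat = _kernels.transport(
        flu,
        float(volume.voxel_size_mm),
        float(props.mu_a),
        float(props.mu_s),
        float(props.g),
        float(props.n),
        float(n_outside),
        np.ascontiguousarray(pts[:, 0]),
        np.ascontiguousarray(pts[:, 1]),
        np.ascontiguousarray(pts[:, 2]),
        source_type == "isotropic",
        int(config.n_photons),
        np.uint64(config.seed & 0xFFFFFFFFFFFFFFFF),
        float(config.time_gate_ns),
        float(config.roulette_threshold),
        float(config.roulette_survival),
        geom_code,
    )
    flu /= config.n_photons * volume.voxel_size_mm**3
    return FluenceField(
        values=flu,
        volume=volume,
        props=props,
        source_position=pts[0].copy() if len(pts) == 1 else pts.mean(axis=0),
        escaped_weight=escaped,
        absorbed_weight=absorbed,
        inflight_weight=inflight,
        n_photons=config.n_photons,
        n_scatter_events=n_scat,
        seed=config.seed,
        geometry=geometry,
        source_type=source_type,
        source_points=pts if len(pts) > 1 else None,
    )


def _effective_reflection_coefficient(n: float) -> float:
    # Groenhuis polynomial approximation to the internal reflection parameter
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


def analytic_fluence(
    props: OpticalProperties | str,
    r: float | None = None,
    geometry: str = "infinite",
    z: float | None = None,
    rho: float = 0.0,
) -> float:
    """Closed-form diffusion-approximation fluence (per unit source power).

    Infinite medium: ``phi(r) = exp(-mu_eff r) / (4 pi D r)`` for an
    isotropic point source at distance ``r``.

    Semi-infinite medium (pencil beam on the surface): extrapolated-boundary
    image construction with the isotropic-equivalent source buried one
    transport mean free path deep, evaluated at depth ``z`` (lateral offset
    ``rho``).  The fluence vanishes on the extrapolated plane by
    construction.
    """
    props = get_preset(props)
    D = props.diffusion_coefficient
    mu_eff = props.mu_eff
    if geometry == "infinite":
        if r is None:
            raise InvalidParameterError("infinite geometry requires r")
        if r <= 0:
            raise SingularInputError("r must be > 0")
        return math.exp(-mu_eff * r) / (4.0 * math.pi * D * r)
    if geometry == "semi-infinite":
        if z is None:
            raise InvalidParameterError("semi-infinite geometry requires z (depth)")
        z0 = props.transport_mfp
        A = (1.0 + _effective_reflection_coefficient(props.n)) / (
            1.0 - _effective_reflection_coefficient(props.n)
        )
        zb = 2.0 * A * D
        r1 = math.hypot(rho, z - z0)
        r2 = math.hypot(rho, z + z0 + 2.0 * zb)
        if r1 == 0 or r2 == 0:
            raise SingularInputError("evaluation point coincides with a source")
        term1 = math.exp(-mu_eff * r1) / r1
        term2 = math.exp(-mu_eff * r2) / r2
        return (term1 - term2) / (4.0 * math.pi * D)
    raise InvalidParameterError(f"unknown geometry {geometry!r}")
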