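"""Synthetic wide-field OCT thickness maps with controllable retinal anatomy.

This module generates 9 x 12 mm wide-field retinal nerve fiber layer (RNFL)
and macular GCL+ (ganglion cell + inner plexiform layer) thickness maps on the
standard 256 x 512 grid, together with labelled cohorts of healthy and
glaucomatous eyes.  The purpose is to make every downstream stage of the
pipeline (normative percentile maps, abnormal-region rules, circumpapillary
metrics) testable without any clinical data.

The generative model
--------------------
Nerve fiber bundles leave the optic disc at an *entry angle* ``phi0`` measured
from the disc->fovea axis and follow arcuate trajectories around the macula::

    phi(r) = phi0 * exp(-beta * (r - r_disc))

in a disc-centred polar frame (``r`` in mm).  The horizontal raphe (the ray
from the fovea directed away from the disc) is a hard boundary: trajectories
never change the sign of ``phi``, so superior-entry fibers stay superior.
The map from a pixel to the entry angle of the fiber passing over it is the
closed-form inverse ``phi0 = theta * exp(beta * (r - r_disc))``, which lets
the whole field be synthesised with vectorised array arithmetic.

RNFL thickness at a pixel is an angular bundle profile evaluated at the
pixel's entry angle (two wrapped-Gaussian arcuate ridges, a papillomacular
plateau and a nasal floor), attenuated radially away from the disc, multiplied
by a foveal-pit mask, plus narrow additive vessel ridges that ride on the
bundles, plus i.i.d. Gaussian measurement noise clipped at zero.

Glaucomatous defects are wedges in entry-angle space: all fibers whose entry
angle falls inside the wedge lose ``depth_fraction`` of their thickness along
their entire trajectory, which is why true arcuate defects extend from the
temporal disc across the vertical midline through the fovea.  Glaucoma-like
*artifacts* in healthy eyes are instead produced by displacing a bundle (and
its vessels) in entry angle, or by a congenitally thin temporal/papillomacular
sector: no tissue is lost, so the mismatch with the normative template is
large near the disc but falls inside the normal range downstream, where
between-eye variation in trajectory curvature dominates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, LandmarkGeometryError
from .geometry import (
    SUPERIOR_SIGN_FIELD,
    SUPERIOR_SIGN_RETINA,
    disc_axes,
    pixel_centers_mm,
    polar_about_disc,
    wrap_angle_deg,
)

# Standard wide-field scan geometry: 256 B-scans (rows) x 512 A-scans (cols)
# covering 9 mm (vertical) x 12 mm (horizontal).
GRID_SHAPE: tuple[int, int] = (256, 512)
SCAN_EXTENT_MM: tuple[float, float] = (9.0, 12.0)
PIXEL_SIZE_MM: tuple[float, float] = (
    SCAN_EXTENT_MM[0] / GRID_SHAPE[0],
    SCAN_EXTENT_MM[1] / GRID_SHAPE[1],
)

# Fixed template shape parameters (per-eye variation lives in EyeAnatomy).
BUNDLE_SIGMA_DEG = 26.0  # angular half-width of the arcuate ridges
PM_SIGMA_DEG = 42.0  # width of the papillomacular plateau
FLOOR_TEMPORAL_SIGMA_DEG = 60.0  # temporal lobe of the floor thinned by temporal_scale
FAN_THETA_DEG_PER_MM = 2.0  # downstream fanning/overlap of bundles
TEMPORAL_THIN_FADE_MM = 2.2  # radial e-fold of congenital temporal thinning
RADIAL_DECAY_MM = 4.0  # e-folding of thickness away from the disc
PIT_SIGMA_MM = 0.55  # foveal pit radius
VESSEL_SIGMA_MM = 0.15  # vessel ridge half-width (perpendicular)
AGE_SLOPE_PER_YEAR = 0.002  # fractional neural loss per year about age 60
GCL_RING_RADIUS_MM = 1.05
GCL_RING_SIGMA_MM = 0.75
GCL_RING_AMP_UM = 85.0
GCL_BASE_UM = 24.0
GCL_EXTENT_MM = 3.2  # macular radius over which glaucomatous GCL+ loss acts


def _gauss_deg(delta_deg: np.ndarray | float, sigma_deg: float) -> np.ndarray:
    d = wrap_angle_deg(delta_deg)
    return np.exp(-0.5 * (np.asarray(d) / sigma_deg) ** 2)


@dataclass
class EyeAnatomy:
    """Landmarks and per-eye anatomical parameters of one eye.

    Positions are millimetres in the eye's *native retina-view* frame
    (top = superior retina; for OD the fovea is at larger x than the disc,
    for OS at smaller x).  ``bundle_peak_angles`` are the entry angles of the
    superior and inferior major arcuate bundles measured from the disc->fovea
    axis (superior positive).  ``vessel_offsets`` displace the vessel ridges
    relative to the bundle peaks, so displaced bundles carry their vessels.
    """

    fovea_center: tuple[float, float] = (8.5, 4.5)
    disc_center: tuple[float, float] = (4.0, 4.5)
    disc_radius: float = 0.92
    laterality: str = "OD"
    age: float = 60.0
    bundle_peak_angles: tuple[float, float] = (76.0, -76.0)
    vessel_offsets: tuple[float, float] = (11.0, -11.0)
    # anatomical parameters beyond the landmark set
    arc_beta: tuple[float, float] = (0.25, 0.25)  # (superior, inferior) curvature 1/mm
    bundle_amplitudes: tuple[float, float] = (125.0, 125.0)  # um
    papillomacular_amplitude: float = 48.0  # um
    base_floor: float = 58.0  # um, diffuse background RNFL
    vessel_amplitude: float = 26.0  # um
    temporal_scale: float = 1.0  # congenital scaling of the temporal plateau

    def validate(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise LandmarkGeometryError(f"laterality must be OD or OS, got {self.laterality!r}")
        h, w = SCAN_EXTENT_MM
        for name, (x, y) in (("fovea", self.fovea_center), ("disc", self.disc_center)):
            if not (0 < x < w and 0 < y < h):
                raise LandmarkGeometryError(f"{name} center {(x, y)} outside the scan frame")
        dx = self.fovea_center[0] - self.disc_center[0]
        if self.laterality == "OD" and dx <= 0:
            raise LandmarkGeometryError("OD eye must have fovea temporal (x>) of the disc")
        if self.laterality == "OS" and dx >= 0:
            raise LandmarkGeometryError("OS eye must have fovea temporal (x<) of the disc")
        if self.disc_radius <= 0:
            raise LandmarkGeometryError("disc_radius must be positive")
        if not (18.0 <= self.age <= 90.0):
            raise LandmarkGeometryError(f"age {self.age} outside [18, 90]")
        sup, inf = self.bundle_peak_angles
        if not (0.0 < sup < 180.0) or not (-180.0 < inf < 0.0):
            raise LandmarkGeometryError(
                f"bundle peaks must be (superior in (0,180), inferior in (-180,0)); got {self.bundle_peak_angles}"
            )
        if min(self.arc_beta) <= 0:
            raise LandmarkGeometryError("arc curvature must be positive")

    def mirrored(self) -> "EyeAnatomy":
        """The same eye reflected about the vertical axis (OD <-> OS)."""
        w = SCAN_EXTENT_MM[1]
        return replace(
            self,
            fovea_center=(w - self.fovea_center[0], self.fovea_center[1]),
            disc_center=(w - self.disc_center[0], self.disc_center[1]),
            laterality="OS" if self.laterality == "OD" else "OD",
        )

    def in_od_frame(self) -> "EyeAnatomy":
        return self if self.laterality == "OD" else self.mirrored()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "EyeAnatomy":
        kwargs = dict(d)
        for key in ("fovea_center", "disc_center", "bundle_peak_angles", "vessel_offsets",
                    "arc_beta", "bundle_amplitudes"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class DefectSpec:
    """Parametric glaucomatous defect acting on entry-angle wedges.

    ``kind``:

    * ``none`` -- healthy.
    * ``arcuate`` -- a single wedge centred at ``wedge_center_angle``.
    * ``diffuse_temporal`` -- a wide wedge about the papillomacular axis.
    * ``combined`` -- the arcuate wedge plus a temporal wedge at 3/4 depth.

    ``depth_fraction`` is the fraction of neural thickness removed along every
    trajectory inside the wedge (vessels are spared, as in real scans).
    """

    kind: str = "none"
    wedge_center_angle: float = 70.0
    wedge_width: float = 30.0
    depth_fraction: float = 0.0
    severity_label: str = "HC"

    def validate(self) -> None:
        if self.kind not in ("none", "arcuate", "diffuse_temporal", "combined"):
            raise ConfigurationError(f"unknown defect kind {self.kind!r}")
        if not (0.0 <= self.depth_fraction <= 1.0):
            raise ConfigurationError("depth_fraction must lie in [0, 1]")
        if self.kind != "none" and self.wedge_width <= 0:
            raise ConfigurationError("wedge_width must be positive for a defect")
        if self.severity_label not in ("HC", "EG", "MG", "AG"):
            raise ConfigurationError(f"unknown severity label {self.severity_label!r}")

    def attenuation(self, phi0: np.ndarray) -> np.ndarray:
        """Fraction of neural thickness removed at each entry angle."""
        self.validate()
        att = np.zeros_like(np.asarray(phi0, dtype=float))
        if self.kind == "none" or self.depth_fraction == 0.0:
            return att
        if self.kind in ("arcuate", "diffuse_temporal"):
            inside = np.abs(wrap_angle_deg(phi0 - self.wedge_center_angle)) <= self.wedge_width / 2
            att[inside] = self.depth_fraction
        elif self.kind == "combined":
            inside = np.abs(wrap_angle_deg(phi0 - self.wedge_center_angle)) <= self.wedge_width / 2
            temporal = np.abs(wrap_angle_deg(phi0)) <= 50.0
            att[temporal] = 0.75 * self.depth_fraction
            att[inside] = np.maximum(att[inside], self.depth_fraction)
        return att


@dataclass
class ThicknessMap:
    """A 2-D layer-thickness grid (um) with physical scale and landmarks.

    ``view`` is ``retina`` (top = superior retina, the native orientation) or
    ``field`` (vertical flip; top = superior visual field).  ``frame`` records
    whether an OS map has been mirrored into the OD reference frame.
    """

    values: np.ndarray
    pixel_size: tuple[float, float] = PIXEL_SIZE_MM
    view: str = "retina"
    anatomy: EyeAnatomy = field(default_factory=EyeAnatomy)
    layer: str = "RNFL"
    frame: str = "native"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("thickness values must be a 2-D grid")
        if self.view not in ("retina", "field"):
            raise ValueError(f"unknown view {self.view!r}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_size[0], self.shape[1] * self.pixel_size[1])

    @property
    def superior_sign(self) -> float:
        return SUPERIOR_SIGN_RETINA if self.view == "retina" else SUPERIOR_SIGN_FIELD

    def _transform_point(self, p: tuple[float, float]) -> tuple[float, float]:
        """Native retina-view anatomy position -> this map's frame/view."""
        from .geometry import landmark_to_frame

        return landmark_to_frame(p, self.anatomy.laterality, self.view, self.frame, self.extent_mm)

    def in_od_frame(self) -> "ThicknessMap":
        """Return this map mirrored into the OD reference frame (no-op for OD)."""
        if self.frame == "OD" or self.anatomy.laterality == "OD":
            return replace(self, frame="OD")
        return replace(self, values=self.values[:, ::-1].copy(), frame="OD")

    @property
    def fovea_mm(self) -> tuple[float, float]:
        return self._transform_point(self.anatomy.fovea_center)

    @property
    def disc_mm(self) -> tuple[float, float]:
        return self._transform_point(self.anatomy.disc_center)

    def pixel_grids_mm(self) -> tuple[np.ndarray, np.ndarray]:
        return pixel_centers_mm(self.shape, self.pixel_size)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("thickness values must be finite")
        if np.any(self.values < 0):
            raise ValueError("thickness values must be non-negative")


def entry_angle_grid(
    anatomy: EyeAnatomy,
    shape: tuple[int, int] = GRID_SHAPE,
    pixel_size: tuple[float, float] = PIXEL_SIZE_MM,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel ``(phi0, r, theta)`` in the eye's native retina frame.

    ``phi0`` is the entry angle (degrees, clipped to +-180) of the fiber
    trajectory passing through each pixel, ``r`` the disc distance in mm and
    ``theta`` the axis-relative angle of the pixel itself.
    """
    X, Y = pixel_centers_mm(shape, pixel_size)
    u, s = disc_axes(anatomy.disc_center, anatomy.fovea_center, SUPERIOR_SIGN_RETINA)
    r, theta = polar_about_disc(X, Y, anatomy.disc_center, u, s)
    dr = np.clip(r - anatomy.disc_radius, 0.0, None)
    beta = np.where(theta >= 0, anatomy.arc_beta[0], anatomy.arc_beta[1])
    mag = np.minimum(np.abs(theta) * np.exp(beta * dr), 180.0)
    phi0 = np.sign(theta) * mag
    return phi0, r, theta


def bundle_trajectory(
    anatomy: EyeAnatomy,
    entry_angle: float,
    step_mm: float = 0.04,
) -> np.ndarray:
    """Trace the fiber-bundle path entering the disc at ``entry_angle``.

    Returns an (N, 2) array of (x, y) mm positions in the native retina
    frame, starting on the disc boundary, truncated at the scan edge or at
    the foveal pit (papillomacular fibers terminate at the fovea).
    """
    anatomy.validate()
    if not (-180.0 < entry_angle < 180.0):
        raise ValueError(f"entry_angle {entry_angle} outside (-180, 180)")
    u, s = disc_axes(anatomy.disc_center, anatomy.fovea_center, SUPERIOR_SIGN_RETINA)
    beta = anatomy.arc_beta[0] if entry_angle >= 0 else anatomy.arc_beta[1]
    h, w = SCAN_EXTENT_MM
    r_max = float(np.hypot(h, w))
    r = np.arange(anatomy.disc_radius, r_max, step_mm)
    phi = np.radians(entry_angle) * np.exp(-beta * (r - anatomy.disc_radius))
    d = np.cos(phi)[:, None] * u[None, :] + np.sin(phi)[:, None] * s[None, :]
    pts = np.asarray(anatomy.disc_center)[None, :] + r[:, None] * d
    inside = (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
    # truncate at first frame exit
    exits = np.nonzero(~inside)[0]
    if exits.size:
        pts = pts[: exits[0]]
    # terminate at the foveal pit
    dfov = np.hypot(pts[:, 0] - anatomy.fovea_center[0], pts[:, 1] - anatomy.fovea_center[1])
    hits = np.nonzero(dfov < 0.25)[0]
    if hits.size:
        pts = pts[: hits[0] + 1]
    return pts


def _fan_widened(sigma_deg: float, dr: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Effective angular width at distance ``dr`` beyond the disc boundary.

    Bundles fan out and overlap away from the disc; in entry-angle
    coordinates a spatial widening of FAN_THETA_DEG_PER_MM per mm maps to a
    widening scaled by exp(beta * dr).  This is what confines a displaced
    bundle's thickness gap to the neighbourhood of the disc while leaving
    true (multiplicative) fiber loss visible along the whole trajectory.
    """
    return np.minimum(sigma_deg + FAN_THETA_DEG_PER_MM * dr * np.exp(beta * dr), 80.0)


def _gauss_var_deg(delta_deg: np.ndarray, sigma_deg: np.ndarray) -> np.ndarray:
    d = wrap_angle_deg(delta_deg)
    return np.exp(-0.5 * (np.asarray(d) / sigma_deg) ** 2)


def _neural_profile(
    anatomy: EyeAnatomy, phi0: np.ndarray, dr: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """Angular thickness profile (um) at entry angles ``phi0``, fan-widened."""
    sup_amp, inf_amp = anatomy.bundle_amplitudes
    sup_peak, inf_peak = anatomy.bundle_peak_angles
    sig_b = _fan_widened(BUNDLE_SIGMA_DEG, dr, beta)
    sig_pm = _fan_widened(PM_SIGMA_DEG, dr, beta)
    # temporal_scale < 1 thins the papillomacular plateau and the temporal
    # lobe of the diffuse floor (tapering off nasally).  The thinning is a
    # property of the papillomacular fiber mass entering the disc, so it
    # fades radially: beyond the fovea the temporal floor is arcuate-tail
    # tissue and is unaffected.
    thin = (1.0 - anatomy.temporal_scale) * np.exp(-0.5 * (dr / TEMPORAL_THIN_FADE_MM) ** 2)
    floor = anatomy.base_floor * (1.0 - thin * _gauss_deg(phi0, FLOOR_TEMPORAL_SIGMA_DEG))
    prof = (
        sup_amp * _gauss_var_deg(phi0 - sup_peak, sig_b)
        + inf_amp * _gauss_var_deg(phi0 - inf_peak, sig_b)
        + anatomy.papillomacular_amplitude * (1.0 - thin) * _gauss_var_deg(phi0, sig_pm)
        + floor
    )
    return prof


def _vessel_field(anatomy: EyeAnatomy, phi0: np.ndarray, r: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Additive vessel ridges following the (possibly displaced) bundles."""
    dr = np.clip(r - anatomy.disc_radius, 0.0, None)
    out = np.zeros_like(phi0)
    for peak, offset, beta in zip(
        anatomy.bundle_peak_angles, anatomy.vessel_offsets, anatomy.arc_beta
    ):
        phi0_v = peak + offset
        same_hemi = np.sign(theta) == np.sign(phi0_v)
        dist = r * np.abs(np.radians(wrap_angle_deg(phi0 - phi0_v))) * np.exp(-beta * dr)
        ridge = anatomy.vessel_amplitude * np.exp(-0.5 * (dist / VESSEL_SIGMA_MM) ** 2)
        ridge *= np.exp(-dr / 10.0)  # vessels taper slowly towards the periphery
        out += np.where(same_hemi, ridge, 0.0)
    return out


def synthesize_thickness_map(
    anatomy: EyeAnatomy,
    defect: DefectSpec | None = None,
    noise_sd: float = 3.0,
    seed: int | None = 0,
    shape: tuple[int, int] = GRID_SHAPE,
    pixel_size: tuple[float, float] = PIXEL_SIZE_MM,
) -> ThicknessMap:
    """Synthesize one RNFL thickness map in the native retina view.

    With ``defect=None``/``kind='none'`` and ``noise_sd=0`` the output is the
    eye's deterministic baseline template.  Identical arguments and seed give
    bit-identical maps.
    """
    anatomy.validate()
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    defect = defect or DefectSpec()
    phi0, r, theta = entry_angle_grid(anatomy, shape, pixel_size)
    dr = np.clip(r - anatomy.disc_radius, 0.0, None)
    beta = np.where(theta >= 0, anatomy.arc_beta[0], anatomy.arc_beta[1])
    neural = _neural_profile(anatomy, phi0, dr, beta)
    neural = neural * (1.0 - defect.attenuation(phi0))
    neural *= 1.0 - AGE_SLOPE_PER_YEAR * (anatomy.age - 60.0)
    neural *= np.exp(-dr / RADIAL_DECAY_MM)
    total = neural + _vessel_field(anatomy, phi0, r, theta)
    X, Y = pixel_centers_mm(shape, pixel_size)
    dfov2 = (X - anatomy.fovea_center[0]) ** 2 + (Y - anatomy.fovea_center[1]) ** 2
    total *= 1.0 - np.exp(-dfov2 / (2.0 * PIT_SIGMA_MM**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        total = total + rng.normal(0.0, noise_sd, size=total.shape)
    values = np.clip(total, 0.0, None).astype(np.float32)
    return ThicknessMap(values, pixel_size, "retina", anatomy, "RNFL")


def synthesize_gcl_map(
    anatomy: EyeAnatomy,
    defect: DefectSpec | None = None,
    noise_sd: float = 3.0,
    seed: int | None = 0,
    shape: tuple[int, int] = GRID_SHAPE,
    pixel_size: tuple[float, float] = PIXEL_SIZE_MM,
) -> ThicknessMap:
    """Synthesize the companion macular GCL+ thickness map.

    The GCL+ donut is centred on the fovea and is *not* affected by bundle or
    vessel displacement (those are RNFL features), but glaucomatous wedges
    remove the ganglion cells feeding the attenuated fibers: macular pixels
    whose overlying trajectory entry angle falls in the defect wedge lose
    ``0.85 * depth_fraction`` of their thickness.
    """
    anatomy.validate()
    defect = defect or DefectSpec()
    X, Y = pixel_centers_mm(shape, pixel_size)
    dfov = np.hypot(X - anatomy.fovea_center[0], Y - anatomy.fovea_center[1])
    base = GCL_BASE_UM + GCL_RING_AMP_UM * np.exp(
        -0.5 * ((dfov - GCL_RING_RADIUS_MM) / GCL_RING_SIGMA_MM) ** 2
    )
    base *= 1.0 - 0.75 * np.exp(-(dfov**2) / (2.0 * 0.30**2))  # foveal depression
    base *= 1.0 - AGE_SLOPE_PER_YEAR * (anatomy.age - 60.0)
    phi0, _, _ = entry_angle_grid(anatomy, shape, pixel_size)
    att = 0.85 * defect.attenuation(phi0) * (dfov <= GCL_EXTENT_MM)
    total = base * (1.0 - att)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        total = total + rng.normal(0.0, noise_sd, size=total.shape)
    values = np.clip(total, 0.0, None).astype(np.float32)
    return ThicknessMap(values, pixel_size, "retina", anatomy, "GCLplus")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

GROUPS = ("HC_norm", "HC", "EG_VF", "MG", "AG")
MECHANISMS = ("arcuate", "temporal_Q", "both")


@dataclass
class AnatomyDistribution:
    """Sampling distribution of healthy anatomy.

    Standard deviations set to zero reproduce the fixed canonical eye, which
    is how spatially independent (noise-only) reference cohorts are made for
    calibration studies.
    """

    fovea_center: tuple[float, float] = (8.5, 4.5)
    fovea_sd: float = 0.10
    disc_center: tuple[float, float] = (4.0, 4.5)
    disc_sd: float = 0.12
    disc_radius: float = 0.92
    disc_radius_sd: float = 0.05
    bundle_peaks: tuple[float, float] = (76.0, -76.0)
    bundle_peak_sd: float = 8.0
    vessel_offsets: tuple[float, float] = (11.0, -11.0)
    vessel_offset_sd: float = 2.0
    arc_beta: float = 0.25
    arc_beta_sd: float = 0.10
    bundle_amp: float = 125.0
    bundle_amp_frac_sd: float = 0.07
    pm_amp: float = 48.0
    pm_amp_frac_sd: float = 0.10
    floor: float = 58.0
    floor_frac_sd: float = 0.06
    vessel_amp: float = 26.0
    vessel_amp_frac_sd: float = 0.15
    age_range: tuple[float, float] = (40.0, 80.0)
    os_fraction: float = 0.5
    # displaced-bundle artifact mechanism
    displacement_deg: tuple[float, float] = (26.0, 40.0)
    temporal_scale_range: tuple[float, float] = (0.38, 0.55)

    def sample(self, rng: np.random.Generator) -> EyeAnatomy:
        def lognorm(mean: float, frac_sd: float) -> float:
            if frac_sd == 0:
                return mean
            return float(mean * np.exp(rng.normal(0.0, frac_sd)))

        fov = (
            self.fovea_center[0] + rng.normal(0, self.fovea_sd) if self.fovea_sd else self.fovea_center[0],
            self.fovea_center[1] + rng.normal(0, self.fovea_sd) if self.fovea_sd else self.fovea_center[1],
        )
        disc = (
            self.disc_center[0] + rng.normal(0, self.disc_sd) if self.disc_sd else self.disc_center[0],
            self.disc_center[1] + rng.normal(0, self.disc_sd) if self.disc_sd else self.disc_center[1],
        )
        peaks = (
            float(np.clip(self.bundle_peaks[0] + (rng.normal(0, self.bundle_peak_sd) if self.bundle_peak_sd else 0.0), 20.0, 160.0)),
            float(np.clip(self.bundle_peaks[1] + (rng.normal(0, self.bundle_peak_sd) if self.bundle_peak_sd else 0.0), -160.0, -20.0)),
        )
        offsets = (
            self.vessel_offsets[0] + (rng.normal(0, self.vessel_offset_sd) if self.vessel_offset_sd else 0.0),
            self.vessel_offsets[1] + (rng.normal(0, self.vessel_offset_sd) if self.vessel_offset_sd else 0.0),
        )
        betas = tuple(
            float(np.clip(self.arc_beta + (rng.normal(0, self.arc_beta_sd) if self.arc_beta_sd else 0.0), 0.08, 0.50))
            for _ in range(2)
        )
        anatomy = EyeAnatomy(
            fovea_center=fov,
            disc_center=disc,
            disc_radius=float(np.clip(self.disc_radius + (rng.normal(0, self.disc_radius_sd) if self.disc_radius_sd else 0.0), 0.6, 1.3)),
            laterality="OS" if rng.random() < self.os_fraction else "OD",
            age=float(rng.uniform(*self.age_range)),
            bundle_peak_angles=peaks,
            vessel_offsets=offsets,
            arc_beta=betas,  # type: ignore[arg-type]
            bundle_amplitudes=(lognorm(self.bundle_amp, self.bundle_amp_frac_sd),
                               lognorm(self.bundle_amp, self.bundle_amp_frac_sd)),
            papillomacular_amplitude=lognorm(self.pm_amp, self.pm_amp_frac_sd),
            base_floor=lognorm(self.floor, self.floor_frac_sd),
            vessel_amplitude=lognorm(self.vessel_amp, self.vessel_amp_frac_sd),
        )
        if anatomy.laterality == "OS":
            anatomy = replace(anatomy.mirrored(), laterality="OS")
        return anatomy

    def apply_mechanism(self, anatomy: EyeAnatomy, mechanism: str, rng: np.random.Generator) -> EyeAnatomy:
        """Inject a glaucoma-like artifact mechanism into a healthy eye."""
        if mechanism in ("arcuate", "both"):
            hemi = int(rng.integers(0, 2))  # 0 = superior, 1 = inferior
            # bundle (and vessels) displaced towards the papillomacular axis,
            # leaving a thickness gap on the high-angle flank of the normal
            # ridge position (an arcuate band over the temporal disc)
            shift = float(rng.uniform(*self.displacement_deg))
            peaks = list(anatomy.bundle_peak_angles)
            # displaced bundles remain arcuate: never closer than 42 deg to
            # the papillomacular axis
            lo, hi = (42.0, 160.0) if hemi == 0 else (-160.0, -42.0)
            peaks[hemi] = float(np.clip(peaks[hemi] - np.sign(peaks[hemi]) * shift, lo, hi))
            anatomy = replace(anatomy, bundle_peak_angles=tuple(peaks))
        if mechanism in ("temporal_Q", "both"):
            anatomy = replace(anatomy, temporal_scale=float(rng.uniform(*self.temporal_scale_range)))
        return anatomy


# defect parameter bands by severity: (width range, depth range, MD range)
SEVERITY_DEFECTS: dict[str, dict] = {
    "EG": {"width": (20.0, 38.0), "depth": (0.40, 0.65), "md": (-5.8, -0.8)},
    "MG": {"width": (40.0, 70.0), "depth": (0.60, 0.80), "md": (-11.5, -6.3)},
    "AG": {"width": (70.0, 115.0), "depth": (0.78, 0.95), "md": (-20.0, -12.3)},
}


@dataclass
class CohortSpec:
    """Description of a labelled synthetic cohort.

    ``group_sizes`` maps group names (``HC_norm``, ``HC``, ``EG_VF``, ``MG``,
    ``AG``) to eye counts.  ``artifact_rate`` is the probability that a
    healthy eye carries a glaucoma-like artifact mechanism; the defaults are
    the empirical frequencies of the two healthy groups (7% of the normative
    sample, 11% of the prospective controls).
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"HC_norm": 200, "HC": 54, "EG_VF": 32, "MG": 12, "AG": 18}
    )
    artifact_rate: Mapping[str, float] | float = field(
        default_factory=lambda: {"HC_norm": 0.07, "HC": 0.11}
    )
    mechanism_probs: tuple[float, float, float] = (0.65, 0.25, 0.10)
    anatomy: AnatomyDistribution = field(default_factory=AnatomyDistribution)
    noise_sd: float = 3.0
    include_gcl: bool = False

    def rate_for(self, group: str) -> float:
        if isinstance(self.artifact_rate, Mapping):
            return float(self.artifact_rate.get(group, 0.0))
        return float(self.artifact_rate) if group in ("HC_norm", "HC") else 0.0

    def validate(self) -> None:
        if not self.group_sizes:
            raise ConfigurationError("cohort spec lists no groups")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}; expected one of {GROUPS}")
            if n < 1:
                raise ConfigurationError(f"group {g!r} needs n >= 1, got {n}")
        if abs(sum(self.mechanism_probs) - 1.0) > 1e-9:
            raise ConfigurationError("mechanism_probs must sum to 1")


@dataclass
class SimulatedEye:
    """One synthetic eye with its ground-truth labels."""

    eye_id: str
    thickness: ThicknessMap
    gcl: ThicknessMap | None
    group: str
    mechanism: str  # 'none' | 'arcuate' | 'temporal_Q' | 'both'
    displaced: bool
    defect: DefectSpec
    md_242: float | None
    abnormal_hemifield: str  # 'superior' | 'inferior' | 'none'


def _sample_defect(group: str, rng: np.random.Generator) -> tuple[DefectSpec, float, str]:
    bands = SEVERITY_DEFECTS[{"EG_VF": "EG"}.get(group, group)]
    sign = 1 if rng.random() < 0.5 else -1
    center = sign * float(rng.uniform(55.0, 85.0))
    width = float(rng.uniform(*bands["width"]))
    depth = float(rng.uniform(*bands["depth"]))
    md = float(rng.uniform(*bands["md"]))
    kind = "arcuate"
    if group == "AG" and rng.random() < 0.5:
        kind = "combined"
    defect = DefectSpec(
        kind=kind,
        wedge_center_angle=center,
        wedge_width=width,
        depth_fraction=depth,
        severity_label={"EG_VF": "EG"}.get(group, group),
    )
    # the abnormal visual-field hemifield is opposite the damaged retina
    hemifield = "inferior" if sign > 0 else "superior"
    return defect, md, hemifield


def generate_cohort(spec: CohortSpec, seed: int = 0) -> list[SimulatedEye]:
    """Generate a labelled cohort of synthetic eyes, reproducible with seed."""
    spec.validate()
    root = np.random.default_rng(seed)
    eyes: list[SimulatedEye] = []
    for group in GROUPS:
        n = int(spec.group_sizes.get(group, 0))
        for i in range(n):
            rng = np.random.default_rng(root.integers(0, 2**31 - 1))
            anatomy = spec.anatomy.sample(rng)
            mechanism = "none"
            displaced = False
            defect = DefectSpec(severity_label="HC")
            md: float | None = None
            hemifield = "none"
            if group in ("HC_norm", "HC"):
                if rng.random() < spec.rate_for(group):
                    mechanism = str(rng.choice(MECHANISMS, p=spec.mechanism_probs))
                    anatomy = spec.anatomy.apply_mechanism(anatomy, mechanism, rng)
                    displaced = mechanism in ("arcuate", "both")
                md = float(rng.uniform(-1.5, 1.5))
            else:
                defect, md, hemifield = _sample_defect(group, rng)
            map_seed = int(rng.integers(0, 2**31 - 1))
            tmap = synthesize_thickness_map(anatomy, defect, spec.noise_sd, map_seed)
            gmap = (
                synthesize_gcl_map(anatomy, defect, spec.noise_sd, map_seed + 1)
                if spec.include_gcl
                else None
            )
            eyes.append(
                SimulatedEye(
                    eye_id=f"{group}_{i:03d}",
                    thickness=tmap,
                    gcl=gmap,
                    group=group,
                    mechanism=mechanism,
                    displaced=displaced,
                    defect=defect,
                    md_242=md,
                    abnormal_hemifield=hemifield,
                )
            )
    return eyes
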