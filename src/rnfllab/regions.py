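"""Abnormal-region extraction and the spatial glaucoma decision rules.

Works on probability maps in field view, OD frame.  Regions are 8-connected
components of abnormal pixels; each carries the geometry flags the decision
rules need:

* *temporal-disc condition* (the necessary condition for calling a map
  glaucomatous): the region intersects an annulus of width ``disc_halo_mm``
  outside the disc boundary, restricted to the temporal half-plane (the half
  containing the fovea).
* *vertical midline crossing*: the region extends contiguously past the
  vertical line through the fovea, by at least ``midline_min_extent_mm`` on
  the far (nasal-field) side.
* *zone membership*: disc-centred angular sectors relative to the disc->fovea
  axis -- temporal quadrant within +-45 deg, superior arcuate (45, 135) deg,
  inferior arcuate (-135, -45) deg.

The artifact taxonomy distinguishes *arcuate* regions (mostly inside an
arcuate sector) from *temporal-quadrant* regions (mostly temporal, touching
the maculopapillary sector between disc and fovea), mirroring the patterns
glaucoma-like artifacts take in healthy eyes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, GridMismatchError, MetadataError
from .geometry import disc_axes, pixel_centers_mm, polar_about_disc
from .normative import ProbabilityMap

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class RuleConfig:
    """Operational parameters of the qualitative decision rules."""

    level: str = "red_only"  # or "red_or_yellow"
    min_area_mm2: float = 0.1
    disc_halo_mm: float = 1.0
    midline_min_extent_mm: float = 0.25
    quadrant_halfangle: float = 45.0

    def validate(self) -> None:
        if self.level not in ("red_only", "red_or_yellow"):
            raise ConfigurationError(f"unknown level {self.level!r}")
        for name in ("min_area_mm2", "disc_halo_mm", "midline_min_extent_mm"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0.0 < self.quadrant_halfangle <= 90.0):
            raise ConfigurationError("quadrant_halfangle must lie in (0, 90]")


@dataclass
class AbnormalRegion:
    """One 8-connected abnormal component with its geometry flags."""

    pixel_set: np.ndarray  # (N, 2) array of (row, col) indices, field view / OD
    area_mm2: float
    touches_temporal_disc: bool
    crosses_midline: bool
    zone_fractions: dict = field(default_factory=dict)
    touches_maculopapillary: bool = False
    nasal_extent_mm: float = 0.0

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_set)


@dataclass
class _Frame:
    """Field-view OD-frame geometry of one eye, shared by the rules."""

    disc: tuple[float, float]
    fovea: tuple[float, float]
    disc_radius: float
    pixel_size: tuple[float, float]

    def pixels_mm(self, pixel_set: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        py, px = self.pixel_size
        y = (pixel_set[:, 0] + 0.5) * py
        x = (pixel_set[:, 1] + 0.5) * px
        return x, y

    def polar(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u, s = disc_axes(self.disc, self.fovea, superior_sign=+1.0)
        return polar_about_disc(x, y, self.disc, u, s)


def _frame_of(pmap: ProbabilityMap) -> _Frame:
    if pmap.view != "field" or pmap.frame != "OD":
        raise MetadataError("decision rules require a field-view, OD-frame probability map")
    return _Frame(pmap.disc_mm, pmap.fovea_mm, pmap.anatomy.disc_radius, pmap.pixel_size)


def _region_from_pixels(pixel_set: np.ndarray, frame: _Frame, config: RuleConfig) -> AbnormalRegion:
    x, y = frame.pixels_mm(pixel_set)
    r, theta = frame.polar(x, y)
    py, px = frame.pixel_size
    area = float(len(pixel_set) * py * px)

    # temporal-disc necessary condition: annulus x temporal half-plane
    u, _ = disc_axes(frame.disc, frame.fovea, superior_sign=+1.0)
    along_axis = (x - frame.disc[0]) * u[0] + (y - frame.disc[1]) * u[1]
    in_annulus = (r >= frame.disc_radius) & (r <= frame.disc_radius + config.disc_halo_mm)
    touches_disc = bool(np.any(in_annulus & (along_axis >= 0)))

    # vertical midline through the fovea; crossing side is away from the disc
    sign = 1.0 if frame.fovea[0] >= frame.disc[0] else -1.0
    beyond = (x - frame.fovea[0]) * sign
    nasal_extent = float(beyond.max()) if np.any(beyond > 0) else 0.0
    crosses = bool(np.any(beyond > 0) and nasal_extent >= config.midline_min_extent_mm)

    qh = config.quadrant_halfangle
    n = len(pixel_set)
    zones = {
        "superior_arcuate": float(np.count_nonzero((theta > qh) & (theta < 180.0 - qh)) / n),
        "inferior_arcuate": float(np.count_nonzero((theta < -qh) & (theta > -(180.0 - qh))) / n),
        "temporal_quadrant": float(np.count_nonzero(np.abs(theta) <= qh) / n),
    }
    dist_df = float(np.hypot(frame.fovea[0] - frame.disc[0], frame.fovea[1] - frame.disc[1]))
    touches_mp = bool(np.any((np.abs(theta) <= qh) & (r <= dist_df)))
    return AbnormalRegion(
        pixel_set=pixel_set,
        area_mm2=area,
        touches_temporal_disc=touches_disc,
        crosses_midline=crosses,
        zone_fractions=zones,
        touches_maculopapillary=touches_mp,
        nasal_extent_mm=nasal_extent,
    )


def regions_from_mask(mask: np.ndarray, frame: _Frame, config: RuleConfig) -> list[AbnormalRegion]:
    """Label an abnormal mask and build regions, largest first."""
    labels, n_labels = ndimage.label(mask, structure=EIGHT_CONNECTED)
    regions: list[AbnormalRegion] = []
    if n_labels == 0:
        return regions
    py, px = frame.pixel_size
    counts = np.bincount(labels.ravel(), minlength=n_labels + 1)
    boxes = ndimage.find_objects(labels)
    for lab, box in enumerate(boxes, start=1):
        if box is None or counts[lab] * py * px < config.min_area_mm2:
            continue
        local = np.argwhere(labels[box] == lab)
        local[:, 0] += box[0].start
        local[:, 1] += box[1].start
        regions.append(_region_from_pixels(local, frame, config))
    regions.sort(key=lambda r: r.area_mm2, reverse=True)
    return regions


def extract_abnormal_regions(pmap: ProbabilityMap, config: RuleConfig | None = None) -> list[AbnormalRegion]:
    """8-connected abnormal components of a probability map, largest first."""
    config = config or RuleConfig()
    config.validate()
    frame = _frame_of(pmap)
    return regions_from_mask(pmap.abnormal_mask(config.level), frame, config)


def temporal_disc_condition(
    region: AbnormalRegion, pmap: ProbabilityMap, config: RuleConfig | None = None
) -> bool:
    """Necessary condition: the region reaches the temporal half of the disc."""
    config = config or RuleConfig()
    frame = _frame_of(pmap)
    return _region_from_pixels(region.pixel_set, frame, config).touches_temporal_disc


def crosses_vertical_midline(
    region: AbnormalRegion, pmap: ProbabilityMap, config: RuleConfig | None = None
) -> bool:
    """Does the region extend contiguously past the vertical line at the fovea?"""
    config = config or RuleConfig()
    frame = _frame_of(pmap)
    return _region_from_pixels(region.pixel_set, frame, config).crosses_midline


def classify_artifact_type(
    regions: Sequence[AbnormalRegion],
    pmap: ProbabilityMap | None = None,
    config: RuleConfig | None = None,
) -> str:
    """Taxonomy of glaucoma-like patterns: none / arcuate / temporal_Q / both.

    Only regions satisfying the temporal-disc necessary condition count.  A
    region is *arcuate* when at least half its area lies in one of the arcuate
    sectors, *temporal_Q* when at least half lies in the temporal quadrant and
    it reaches the maculopapillary sector between disc and fovea.
    """
    qualifying = [r for r in regions if r.touches_temporal_disc]
    arcuate = any(
        max(r.zone_fractions.get("superior_arcuate", 0.0), r.zone_fractions.get("inferior_arcuate", 0.0)) >= 0.5
        for r in qualifying
    )
    temporal = any(
        r.zone_fractions.get("temporal_quadrant", 0.0) >= 0.5 and r.touches_maculopapillary
        for r in qualifying
    )
    if arcuate and temporal:
        return "both"
    if arcuate:
        return "arcuate"
    if temporal:
        return "temporal_Q"
    return "none"


def vertical_midline_rule(
    pmap: ProbabilityMap,
    config: RuleConfig | None = None,
    gcl_pmap: ProbabilityMap | None = None,
) -> str:
    """The vertical midline rule: 'positive' (glaucoma call) or 'negative'.

    Positive iff some abnormal region satisfying the temporal-disc necessary
    condition crosses the vertical midline through the fovea.  When a GCL+
    probability map is supplied, the crossing test runs on the connected
    components of the union of both abnormal masks (the combined variant).
    """
    config = config or RuleConfig()
    config.validate()
    frame = _frame_of(pmap)
    mask = pmap.abnormal_mask(config.level)
    if gcl_pmap is not None:
        if gcl_pmap.shape != pmap.shape or gcl_pmap.pixel_size != pmap.pixel_size:
            raise GridMismatchError("GCL+ probability map is not aligned with the RNFL map")
        if gcl_pmap.view != "field" or gcl_pmap.frame != "OD":
            raise MetadataError("GCL+ probability map must be in field view, OD frame")
        mask = mask | gcl_pmap.abnormal_mask(config.level)
    regions = regions_from_mask(mask, frame, config)
    positive = any(r.touches_temporal_disc and r.crosses_midline for r in regions)
    return "positive" if positive else "negative"
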