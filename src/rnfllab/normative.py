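"""Age-corrected normative model and per-pixel probability (percentile) maps.

A normative model is built from a healthy reference cohort by regressing each
pixel's thickness on age (ordinary least squares) and keeping the full table
of reference residuals at every pixel.  A patient map is converted into a
probability map by ranking its age-corrected residual inside the reference
residual table: with ``n`` reference eyes, a new observation that sits below
``r`` residuals (tied with ``s``) receives percentile

    p = (r + 1 + s/2) * 100 / (n + 1)

the midrank of the observation once inserted into the table.  The smallest
attainable percentile is ``100 / (n + 1)``.  Categories follow the universal
commercial convention: *abnormal* ("red") below the 1st percentile and
*borderline* ("yellow") below the 5th, both configurable.

Probability maps are stored in field view (top = superior visual field,
i.e. inferior retina), mirrored into the right-eye (OD) frame, which is the
orientation every downstream decision rule assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import GridMismatchError, InsufficientReferenceError, MetadataError
from .geometry import SUPERIOR_SIGN_FIELD, SUPERIOR_SIGN_RETINA, landmark_to_frame
from .simulate import EyeAnatomy, ThicknessMap

CAT_NORMAL, CAT_BORDERLINE, CAT_ABNORMAL = 0, 1, 2
CATEGORY_NAMES = {CAT_NORMAL: "normal", CAT_BORDERLINE: "borderline", CAT_ABNORMAL: "abnormal"}


@dataclass
class NormativeModel:
    """Per-pixel age regression plus residual quantile tables."""

    slope: np.ndarray  # um / year, (H, W)
    intercept: np.ndarray  # um at age 0, (H, W)
    residuals_sorted: np.ndarray  # (n_reference, H, W), ascending along axis 0
    n_reference: int
    age_range: tuple[float, float]
    layer: str = "RNFL"
    pixel_size: tuple[float, float] = (9.0 / 256, 12.0 / 512)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slope.shape

    def predicted(self, age: float) -> np.ndarray:
        return self.intercept + self.slope * age


def fit_normative_model(
    reference_maps: Sequence[ThicknessMap],
    min_reference: int = 20,
    min_age_span: float = 10.0,
) -> NormativeModel:
    """Fit the per-pixel normative model from healthy reference maps.

    All maps are mirrored into the OD retina frame before fitting.  If the
    reference ages span less than ``min_age_span`` years the age slope is
    fixed at zero (with a warning) and the intercept is the pixel mean.
    """
    n = len(reference_maps)
    if n < min_reference:
        raise InsufficientReferenceError(
            f"{n} reference eyes < configured floor {min_reference}"
        )
    maps = [m.in_od_frame() for m in reference_maps]
    shape = maps[0].shape
    pixel_size = maps[0].pixel_size
    layer = maps[0].layer
    for m in maps:
        if m.shape != shape or m.pixel_size != pixel_size or m.layer != layer:
            raise GridMismatchError("reference maps differ in grid shape, scale or layer")
        if m.view != "retina":
            raise MetadataError("reference maps must be in retina view")
    ages = np.array([m.anatomy.age for m in maps], dtype=np.float64)
    Y = np.stack([np.asarray(m.values, dtype=np.float64) for m in maps], axis=0)
    Yf = Y.reshape(n, -1)
    span = float(ages.max() - ages.min())
    if span < min_age_span:
        warnings.warn(
            f"reference age span {span:.1f} y < {min_age_span} y; age slope fixed at 0",
            stacklevel=2,
        )
        slope = np.zeros(shape, dtype=np.float32)
        intercept = Yf.mean(axis=0).reshape(shape).astype(np.float32)
    else:
        X = np.column_stack([np.ones(n), ages])
        beta, *_ = np.linalg.lstsq(X, Yf, rcond=None)
        intercept = beta[0].reshape(shape).astype(np.float32)
        slope = beta[1].reshape(shape).astype(np.float32)
    pred = intercept[None].astype(np.float64) + slope[None].astype(np.float64) * ages[:, None, None]
    residuals = np.sort((Y - pred).astype(np.float32), axis=0)
    return NormativeModel(
        slope=slope,
        intercept=intercept,
        residuals_sorted=residuals,
        n_reference=n,
        age_range=(float(ages.min()), float(ages.max())),
        layer=layer,
        pixel_size=pixel_size,
    )


@dataclass
class ProbabilityMap:
    """Per-pixel percentile grid with categorical abnormality levels."""

    percentile: np.ndarray  # in [0, 100]
    category: np.ndarray  # CAT_* codes
    anatomy: EyeAnatomy
    layer: str = "RNFL"
    pixel_size: tuple[float, float] = (9.0 / 256, 12.0 / 512)
    view: str = "field"
    frame: str = "OD"
    red_threshold: float = 1.0
    yellow_threshold: float = 5.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.percentile.shape

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_size[0], self.shape[1] * self.pixel_size[1])

    @property
    def superior_sign(self) -> float:
        return SUPERIOR_SIGN_RETINA if self.view == "retina" else SUPERIOR_SIGN_FIELD

    @property
    def fovea_mm(self) -> tuple[float, float]:
        return landmark_to_frame(
            self.anatomy.fovea_center, self.anatomy.laterality, self.view, self.frame, self.extent_mm
        )

    @property
    def disc_mm(self) -> tuple[float, float]:
        return landmark_to_frame(
            self.anatomy.disc_center, self.anatomy.laterality, self.view, self.frame, self.extent_mm
        )

    def abnormal_mask(self, level: str = "red_only") -> np.ndarray:
        """Boolean mask of abnormal pixels at the requested level."""
        if level == "red_only":
            return self.category == CAT_ABNORMAL
        if level == "red_or_yellow":
            return self.category >= CAT_BORDERLINE
        raise ValueError(f"unknown level {level!r}")


def categorize(percentile: np.ndarray, red: float, yellow: float) -> np.ndarray:
    """Deterministic category grid from a percentile grid and thresholds."""
    cat = np.full(percentile.shape, CAT_NORMAL, dtype=np.int8)
    cat[percentile < yellow] = CAT_BORDERLINE
    cat[percentile < red] = CAT_ABNORMAL
    return cat


def percentile_of(values: np.ndarray, residuals_sorted: np.ndarray) -> np.ndarray:
    """Midrank percentile of observations against sorted reference tables.

    ``values`` has shape (H, W); ``residuals_sorted`` (n, H, W).
    """
    n = residuals_sorted.shape[0]
    v = values[None, ...]
    below = (residuals_sorted < v).sum(axis=0)
    ties = (residuals_sorted == v).sum(axis=0)
    return ((below + 1.0 + ties / 2.0) * (100.0 / (n + 1))).astype(np.float64)


def compute_pmap(
    tmap: ThicknessMap,
    model: NormativeModel,
    red_threshold: float = 1.0,
    yellow_threshold: float = 5.0,
) -> ProbabilityMap:
    """Convert a thickness map into a field-view, OD-frame probability map."""
    if not (0.0 < red_threshold < yellow_threshold < 50.0):
        raise ValueError("need 0 < red_threshold < yellow_threshold < 50")
    od = tmap.in_od_frame()
    if od.view != "retina":
        raise MetadataError("compute_pmap expects a retina-view thickness map")
    if od.shape != model.shape or od.pixel_size != model.pixel_size:
        raise GridMismatchError(
            f"map grid {od.shape}/{od.pixel_size} does not match model {model.shape}/{model.pixel_size}"
        )
    if od.layer != model.layer:
        raise GridMismatchError(f"map layer {od.layer} does not match model layer {model.layer}")
    resid = np.asarray(od.values, dtype=np.float32) - model.predicted(od.anatomy.age).astype(np.float32)
    pct = percentile_of(resid, model.residuals_sorted)
    # retina -> field view: vertical flip
    pct = pct[::-1].copy()
    cat = categorize(pct, red_threshold, yellow_threshold)
    return ProbabilityMap(
        percentile=pct,
        category=cat,
        anatomy=od.anatomy,
        layer=od.layer,
        pixel_size=od.pixel_size,
        view="field",
        frame="OD",
        red_threshold=red_threshold,
        yellow_threshold=yellow_threshold,
    )


def field_view(obj, laterality: str | None = None):
    """Toggle a map between its native retina view and the field view/OD frame.

    Retina-view input is vertically flipped (and OS maps mirrored into the OD
    frame); field-view input is converted back.  The operation is involutive:
    applying it twice returns the original grids.
    """
    anatomy = getattr(obj, "anatomy", None)
    if anatomy is None:
        raise MetadataError("object carries no anatomy metadata")
    lat = laterality or anatomy.laterality
    if lat not in ("OD", "OS"):
        raise MetadataError(f"unknown laterality {lat!r}")

    if isinstance(obj, ThicknessMap):
        names = ("values",)
    elif isinstance(obj, ProbabilityMap):
        names = ("percentile", "category")
    else:
        raise TypeError(f"cannot convert object of type {type(obj).__name__}")

    def flip(a: np.ndarray, mirror: bool) -> np.ndarray:
        a = a[::-1]
        if mirror:
            a = a[:, ::-1]
        return a.copy()

    if obj.view == "retina":
        mirror = lat == "OS" and obj.frame != "OD"
        new = {nm: flip(getattr(obj, nm), mirror) for nm in names}
        return replace(obj, view="field", frame="OD" if (mirror or lat == "OD") else obj.frame, **new)
    # field -> retina: undo in reverse order
    mirror = lat == "OS" and obj.frame == "OD"
    new = {nm: flip(getattr(obj, nm), mirror) for nm in names}
    return replace(obj, view="retina", frame="native" if mirror else obj.frame, **new)
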