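"""Circumpapillary RNFL profile on the 3.4-mm circle and summary metrics.

The circumpapillary profile samples the thickness map on a circle of 3.4 mm
diameter centred on the optic disc, by bilinear interpolation at 256 equally
spaced angles in TSNIT order: starting temporal (on the disc->fovea axis) and
proceeding through superior, nasal and inferior, in the OD frame.  The global
circumpapillary thickness G_cpRNFL is the arithmetic mean of the samples; it
is the single most common OCT summary of glaucomatous damage, and the 5th
percentile of a healthy reference distribution is its conventional
abnormality cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InsufficientReferenceError
from .geometry import SUPERIOR_SIGN_RETINA, disc_axes
from .simulate import ThicknessMap

N_SAMPLES_DEFAULT = 256
CIRCLE_DIAMETER_MM = 3.4


@dataclass
class CircleProfile:
    """Thickness (um) sampled on the circumpapillary circle in TSNIT order."""

    thickness_by_angle: np.ndarray  # (n,) um, angles k * 360/n from temporal
    diameter_mm: float
    center: tuple[float, float]  # disc centre, mm, OD retina frame

    @property
    def angles_deg(self) -> np.ndarray:
        n = len(self.thickness_by_angle)
        return np.arange(n) * (360.0 / n)


@dataclass
class EyeMetrics:
    """Per-eye circumpapillary summary."""

    g_cprnfl: float  # um
    percentile_vs_norm: float  # percent
    below_5th: bool


def extract_circle_profile(
    tmap: ThicknessMap,
    n_samples: int = N_SAMPLES_DEFAULT,
    diameter_mm: float = CIRCLE_DIAMETER_MM,
) -> CircleProfile:
    """Bilinearly sample the 3.4-mm circumpapillary circle, TSNIT order."""
    od = tmap.in_od_frame()
    if od.view != "retina":
        raise ValueError("extract_circle_profile expects a retina-view map")
    radius = diameter_mm / 2.0
    disc = od.disc_mm
    h_mm, w_mm = od.extent_mm
    margins = {
        "left": disc[0] - radius,
        "right": w_mm - disc[0] - radius,
        "top": disc[1] - radius,
        "bottom": h_mm - disc[1] - radius,
    }
    bad = {k: v for k, v in margins.items() if v < 0}
    if bad:
        worst = min(bad, key=bad.get)
        raise ValueError(
            f"circumpapillary circle exits the scan frame at the {worst} edge "
            f"by {-bad[worst]:.2f} mm"
        )
    u, s = disc_axes(disc, od.fovea_mm, SUPERIOR_SIGN_RETINA)
    ang = np.radians(np.arange(n_samples) * (360.0 / n_samples))
    x = disc[0] + radius * (np.cos(ang) * u[0] + np.sin(ang) * s[0])
    y = disc[1] + radius * (np.cos(ang) * u[1] + np.sin(ang) * s[1])
    py, px = od.pixel_size
    rows = y / py - 0.5
    cols = x / px - 0.5
    samples = ndimage.map_coordinates(
        np.asarray(od.values, dtype=np.float64), [rows, cols], order=1, mode="nearest"
    )
    return CircleProfile(samples, diameter_mm, disc)


def global_cprnfl(profile: CircleProfile) -> float:
    """Global (average) circumpapillary thickness, um."""
    return float(np.mean(profile.thickness_by_angle))


def percentile_cutoff(values, q: float = 5.0) -> float:
    """Empirical q-th percentile of reference values (midrank interpolation).

    Uses the Weibull plotting position k/(n+1), consistent with the midrank
    percentile convention of the probability maps.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 20:
        raise InsufficientReferenceError(f"{v.size} reference values < 20")
    return float(np.quantile(v, q / 100.0, method="weibull"))


def percentile_within(value: float, reference) -> float:
    """Midrank percentile of a value within a reference sample."""
    ref = np.asarray(reference, dtype=np.float64)
    below = int(np.count_nonzero(ref < value))
    ties = int(np.count_nonzero(ref == value))
    return (below + 1.0 + ties / 2.0) * 100.0 / (ref.size + 1)


def eye_metrics(g_cprnfl: float, reference_values, q: float = 5.0) -> EyeMetrics:
    """Summary metrics of one eye against a healthy reference distribution."""
    cutoff = percentile_cutoff(reference_values, q)
    return EyeMetrics(
        g_cprnfl=float(g_cprnfl),
        percentile_vs_norm=percentile_within(g_cprnfl, reference_values),
        below_5th=bool(g_cprnfl < cutoff),
    )
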