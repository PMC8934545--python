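"""Shared coordinate conventions and disc-centered geometry helpers.

Conventions used throughout the package
---------------------------------------
* Grids are row-major, origin at the upper-left pixel; positions are given in
  millimetres with the half-open pixel convention (pixel centre of ``[i, j]``
  is at ``((j + 0.5) * px_col, (i + 0.5) * px_row)``).
* ``x`` increases along columns (to the right), ``y`` increases along rows
  (downwards on screen).
* *Retina view*: the top of the grid is the superior retina, so the superior
  anatomical direction is ``-y``.  *Field view* is the vertical flip (top =
  superior visual field = inferior retina), so superior retina is ``+y``.
* In the right-eye (OD) reference frame the fovea lies temporal to the disc at
  larger ``x``.  Left eyes (OS) are mirrored about the vertical axis; all
  decision geometry runs in the OD field-view frame.
* Disc-relative angles are measured from the disc→fovea axis, positive towards
  the superior retina, in degrees, in ``(-180, 180]``.
"""

from __future__ import annotations

import numpy as np

SUPERIOR_SIGN_RETINA = -1.0  # superior retina towards smaller y (top of grid)
SUPERIOR_SIGN_FIELD = +1.0  # after the vertical flip it points towards larger y


def wrap_angle_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (degrees) into ``(-180, 180]``."""
    wrapped = -((-np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0)
    return wrapped


def pixel_centers_mm(shape: tuple[int, int], pixel_size: tuple[float, float]):
    """Return ``(X, Y)`` arrays of pixel-centre positions in mm for a grid.

    ``pixel_size`` is ``(mm per row, mm per column)``.
    """
    rows, cols = shape
    py, px = pixel_size
    x = (np.arange(cols) + 0.5) * px
    y = (np.arange(rows) + 0.5) * py
    return np.meshgrid(x, y)


def disc_axes(
    disc_center: tuple[float, float],
    fovea_center: tuple[float, float],
    superior_sign: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors of the disc-centred frame.

    Returns ``(u, s)`` where ``u`` points from the disc towards the fovea
    (the temporal direction / papillomacular axis) and ``s`` is the in-plane
    perpendicular pointing towards the superior retina.  ``superior_sign`` is
    the sign of the screen-``y`` component of the superior direction
    (:data:`SUPERIOR_SIGN_RETINA` or :data:`SUPERIOR_SIGN_FIELD`).
    """
    d = np.asarray(fovea_center, dtype=float) - np.asarray(disc_center, dtype=float)
    norm = float(np.hypot(*d))
    if norm == 0.0:
        raise ValueError("fovea and disc centers coincide")
    u = d / norm
    s = np.array([-u[1], u[0]])
    if s[1] * superior_sign < 0 or (s[1] == 0 and s[0] != 0):
        s = -s
    # guard the degenerate vertical-axis case: pick s to satisfy the sign
    if s[1] * superior_sign < 0:
        s = -s
    return u, s


def landmark_to_frame(
    p: tuple[float, float],
    laterality: str,
    view: str,
    frame: str,
    extent_mm: tuple[float, float],
) -> tuple[float, float]:
    """Map a native retina-view landmark into a map's (view, frame)."""
    x, y = p
    h, w = extent_mm
    if frame == "OD" and laterality == "OS":
        x = w - x
    if view == "field":
        y = h - y
    return (x, y)


def polar_about_disc(
    x: np.ndarray,
    y: np.ndarray,
    disc_center: tuple[float, float],
    u: np.ndarray,
    s: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Radius (mm) and axis-relative angle (degrees) of points about the disc."""
    vx = np.asarray(x, dtype=float) - disc_center[0]
    vy = np.asarray(y, dtype=float) - disc_center[1]
    r = np.hypot(vx, vy)
    theta = np.degrees(np.arctan2(vx * s[0] + vy * s[1], vx * u[0] + vy * u[1]))
    return r, theta
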