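"""Shared fixtures: canonical anatomy, toy probability maps, reference models."""

from __future__ import annotations

import numpy as np
import pytest

from rnfllab.normative import ProbabilityMap, categorize
from rnfllab.simulate import EyeAnatomy, ThicknessMap

# reduced-resolution grid covering the same 9 x 12 mm extent; everything in
# the generative model scales with physical size, so cheap tests can use it
SMALL_SHAPE = (64, 128)
SMALL_PIXEL = (9.0 / 64, 12.0 / 128)

# toy grid for hand-constructed region geometry (0.125 mm square pixels)
TOY_SHAPE = (72, 96)
TOY_PIXEL = (0.125, 0.125)


@pytest.fixture
def anatomy() -> EyeAnatomy:
    return EyeAnatomy()


def make_toy_pmap(red_mask: np.ndarray, anatomy: EyeAnatomy | None = None) -> ProbabilityMap:
    """Field-view OD-frame probability map with the given red pixels."""
    anatomy = anatomy or EyeAnatomy()
    pct = np.full(red_mask.shape, 50.0)
    pct[red_mask] = 0.5
    return ProbabilityMap(
        percentile=pct,
        category=categorize(pct, 1.0, 5.0),
        anatomy=anatomy,
        pixel_size=TOY_PIXEL,
        view="field",
        frame="OD",
    )


def constant_map(value: float, anatomy: EyeAnatomy | None = None,
                 shape=TOY_SHAPE, pixel_size=TOY_PIXEL, age: float | None = None,
                 layer: str = "RNFL") -> ThicknessMap:
    anatomy = anatomy or EyeAnatomy()
    if age is not None:
        import dataclasses

        anatomy = dataclasses.replace(anatomy, age=age)
    return ThicknessMap(
        np.full(shape, value, dtype=np.float32), pixel_size, "retina", anatomy, layer
    )
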