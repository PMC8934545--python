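"""Region extraction and the spatial decision rules on constructed maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rnfllab.errors import MetadataError
from rnfllab.normative import field_view
from rnfllab.regions import (
    RuleConfig,
    classify_artifact_type,
    crosses_vertical_midline,
    extract_abnormal_regions,
    temporal_disc_condition,
    vertical_midline_rule,
)
from rnfllab.simulate import DefectSpec, EyeAnatomy, synthesize_thickness_map

from conftest import TOY_PIXEL, TOY_SHAPE, make_toy_pmap


def flood_fill_regions(mask: np.ndarray) -> list[set]:
    """Brute-force 8-connected component oracle."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                stack, comp = [(i, j)], set()
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    comp.add((a, b))
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            x, y = a + da, b + db
                            if (
                                0 <= x < mask.shape[0]
                                and 0 <= y < mask.shape[1]
                                and mask[x, y]
                                and not seen[x, y]
                            ):
                                seen[x, y] = True
                                stack.append((x, y))
                comps.append(comp)
    return comps


NO_MIN_AREA = RuleConfig(min_area_mm2=0.0)


class TestExtraction:
    def test_all_normal_gives_empty_list(self):
        pmap = make_toy_pmap(np.zeros(TOY_SHAPE, dtype=bool))
        assert extract_abnormal_regions(pmap) == []

    def test_two_separated_blocks_give_two_equal_regions(self):
        mask = np.zeros(TOY_SHAPE, dtype=bool)
        mask[10:13, 10:13] = True
        mask[10:13, 20:23] = True
        regions = extract_abnormal_regions(make_toy_pmap(mask), NO_MIN_AREA)
        assert len(regions) == 2
        assert regions[0].area_mm2 == pytest.approx(regions[1].area_mm2)
        assert regions[0].n_pixels == 9

    def test_diagonal_chain_is_single_region(self):
        mask = np.zeros(TOY_SHAPE, dtype=bool)
        for k in range(10):
            mask[5 + k, 5 + k] = True
        regions = extract_abnormal_regions(make_toy_pmap(mask), NO_MIN_AREA)
        assert len(regions) == 1
        assert regions[0].n_pixels == 10

    def test_min_area_filters_specks(self):
        mask = np.zeros(TOY_SHAPE, dtype=bool)
        mask[3, 3] = True  # one 0.0156 mm2 pixel
        mask[30:36, 30:36] = True  # 0.56 mm2 block
        regions = extract_abnormal_regions(make_toy_pmap(mask), RuleConfig(min_area_mm2=0.1))
        assert len(regions) == 1 and regions[0].n_pixels == 36

    def test_retina_view_pmap_rejected(self):
        pmap = make_toy_pmap(np.zeros(TOY_SHAPE, dtype=bool))
        retina = field_view(pmap)
        with pytest.raises(MetadataError):
            extract_abnormal_regions(retina)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            dtype=bool,
            shape=st.tuples(st.integers(2, 32), st.integers(2, 32)),
            elements=st.booleans(),
        )
    )
    def test_matches_flood_fill_oracle(self, mask):
        """Connected components agree with a brute-force flood fill."""
        full = np.zeros(TOY_SHAPE, dtype=bool)
        full[: mask.shape[0], : mask.shape[1]] = mask
        regions = extract_abnormal_regions(make_toy_pmap(full), NO_MIN_AREA)
        oracle = flood_fill_regions(full)
        assert len(regions) == len(oracle)
        got = {frozenset((int(a), int(b)) for a, b in r.pixel_set) for r in regions}
        want = {frozenset(c) for c in oracle}
        assert got == want


def _mm_to_px(x_mm: float, y_mm: float) -> tuple[int, int]:
    return int(y_mm / TOY_PIXEL[0]), int(x_mm / TOY_PIXEL[1])


class TestTemporalDiscCondition:
    def test_region_nasal_to_disc_fails(self):
        # default anatomy: disc at (4.0, 4.5), fovea at (8.5, 4.5): nasal is x < 4
        mask = np.zeros(TOY_SHAPE, dtype=bool)
        r, c = _mm_to_px(2.6, 4.5)
        mask[r - 2 : r + 2, c - 2 : c + 2] = True
        pmap = make_toy_pmap(mask)
        (region,) = extract_abnormal_regions(pmap, NO_MIN_AREA)
        assert temporal_disc_condition(region, pmap) is False

    def test_pixel_on_temporal_boundary_passes(self):
        mask = np.zeros(TOY_SHAPE, dtype=bool)
        mask[_mm_to_px(4.0 + 0.95, 4.5)] = True  # just outside the 0.92 mm disc
        pmap = make_toy_pmap(mask)
        (region,) = extract_abnormal_regions(pmap, NO_MIN_AREA)
        assert temporal_disc_condition(region, pmap) is True

    def test_region_outside_halo_fails(self):
        mask = np.zeros(TOY_SHAPE, dtype=bool)
        mask[_mm_to_px(6.8, 4.5)] = True  # 2.8 mm from disc center > 0.92 + 1.0
        pmap = make_toy_pmap(mask)
        (region,) = extract_abnormal_regions(pmap, NO_MIN_AREA)
        assert temporal_disc_condition(region, pmap) is False


class TestMidline:
    def _band(self, x_stop_mm: float) -> np.ndarray:
        """Horizontal band from the temporal disc out to x_stop_mm."""
        mask = np.zeros(TOY_SHAPE, dtype=bool)
        r0, c0 = _mm_to_px(5.0, 3.9)
        _, c1 = _mm_to_px(x_stop_mm, 3.9)
        mask[r0 : r0 + 3, c0:c1] = True
        return mask

    def test_band_crossing_two_mm_past_fovea_is_positive(self):
        pmap = make_toy_pmap(self._band(10.5))
        (region,) = extract_abnormal_regions(pmap, NO_MIN_AREA)
        cfg = RuleConfig(min_area_mm2=0.0, midline_min_extent_mm=0.5)
        assert crosses_vertical_midline(region, pmap, cfg) is True
        assert vertical_midline_rule(pmap, cfg) == "positive"

    def test_band_stopping_short_is_negative(self):
        pmap = make_toy_pmap(self._band(8.3))  # fovea_x = 8.5
        (region,) = extract_abnormal_regions(pmap, NO_MIN_AREA)
        assert crosses_vertical_midline(region, pmap) is False
        assert vertical_midline_rule(pmap, NO_MIN_AREA) == "negative"

    def test_grazing_below_min_extent_is_negative(self):
        pmap = make_toy_pmap(self._band(8.6))  # 0.1 mm past < 0.25 mm required
        (region,) = extract_abnormal_regions(pmap, NO_MIN_AREA)
        assert crosses_vertical_midline(region, pmap) is False

    def test_all_normal_is_negative(self):
        pmap = make_toy_pmap(np.zeros(TOY_SHAPE, dtype=bool))
        assert vertical_midline_rule(pmap) == "negative"


class TestClassification:
    def test_no_qualifying_regions_gives_none(self):
        mask = np.zeros(TOY_SHAPE, dtype=bool)
        r, c = _mm_to_px(2.6, 4.5)
        mask[r - 2 : r + 2, c - 2 : c + 2] = True  # nasal only
        pmap = make_toy_pmap(mask)
        regions = extract_abnormal_regions(pmap, NO_MIN_AREA)
        assert classify_artifact_type(regions, pmap) == "none"

    def _sector_mask(self, theta_lo, theta_hi, r_lo=1.0, r_hi=2.6):
        """Disc-centred sector in field-view coordinates (superior = +y)."""
        yy, xx = np.mgrid[0 : TOY_SHAPE[0], 0 : TOY_SHAPE[1]]
        x = (xx + 0.5) * TOY_PIXEL[1] - 4.0
        y = (yy + 0.5) * TOY_PIXEL[0] - 4.5
        r = np.hypot(x, y)
        theta = np.degrees(np.arctan2(y, x))  # +y is superior in field view
        return (r >= r_lo) & (r <= r_hi) & (theta >= theta_lo) & (theta <= theta_hi)

    def test_superior_sector_region_is_arcuate(self):
        pmap = make_toy_pmap(self._sector_mask(50, 110))
        regions = extract_abnormal_regions(pmap, NO_MIN_AREA)
        assert classify_artifact_type(regions, pmap) == "arcuate"

    def test_temporal_sector_region_is_temporal_q(self):
        pmap = make_toy_pmap(self._sector_mask(-35, 35, 1.0, 2.2))
        regions = extract_abnormal_regions(pmap, NO_MIN_AREA)
        assert classify_artifact_type(regions, pmap) == "temporal_Q"

    def test_disjoint_arcuate_and_temporal_regions_give_both(self):
        mask = self._sector_mask(55, 110) | self._sector_mask(-30, 30, 1.0, 2.0)
        pmap = make_toy_pmap(mask)
        regions = extract_abnormal_regions(pmap, NO_MIN_AREA)
        assert classify_artifact_type(regions, pmap) == "both"


class TestCombinedRule:
    def test_gcl_extension_turns_rule_positive(self):
        """An RNFL arcuate ending at the midline plus a GCL+ region continuing
        nasally: the union crosses while the RNFL map alone does not."""
        rnfl = np.zeros(TOY_SHAPE, dtype=bool)
        r0, c0 = _mm_to_px(5.0, 3.0)
        _, c1 = _mm_to_px(8.3, 3.0)
        rnfl[r0 : r0 + 3, c0:c1] = True
        gcl = np.zeros(TOY_SHAPE, dtype=bool)
        _, g0 = _mm_to_px(7.8, 3.0)
        _, g1 = _mm_to_px(9.6, 3.0)
        gcl[r0 - 1 : r0 + 4, g0:g1] = True
        pmap, gcl_pmap = make_toy_pmap(rnfl), make_toy_pmap(gcl)
        assert vertical_midline_rule(pmap) == "negative"
        assert vertical_midline_rule(pmap, gcl_pmap=gcl_pmap) == "positive"

    def test_disconnected_gcl_region_does_not_help(self):
        rnfl = np.zeros(TOY_SHAPE, dtype=bool)
        r0, c0 = _mm_to_px(5.0, 3.0)
        _, c1 = _mm_to_px(7.0, 3.0)
        rnfl[r0 : r0 + 3, c0:c1] = True
        gcl = np.zeros(TOY_SHAPE, dtype=bool)
        _, g0 = _mm_to_px(8.7, 3.0)
        _, g1 = _mm_to_px(9.6, 3.0)
        gcl[r0 : r0 + 3, g0:g1] = True  # gap between 7.0 and 8.7 mm
        assert vertical_midline_rule(make_toy_pmap(rnfl), gcl_pmap=make_toy_pmap(gcl)) == "negative"


class TestInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rule_monotone_under_mask_growth(self, seed):
        """Enlarging the abnormal mask never flips the rules positive->negative."""
        from scipy import ndimage

        rng = np.random.default_rng(seed)
        mask = np.zeros(TOY_SHAPE, dtype=bool)
        for _ in range(rng.integers(1, 4)):
            r, c = rng.integers(5, TOY_SHAPE[0] - 9), rng.integers(5, TOY_SHAPE[1] - 9)
            mask[r : r + rng.integers(2, 9), c : c + rng.integers(2, 9)] = True
        grown = ndimage.binary_dilation(mask, iterations=2)
        pm0, pm1 = make_toy_pmap(mask), make_toy_pmap(grown)
        if vertical_midline_rule(pm0, NO_MIN_AREA) == "positive":
            assert vertical_midline_rule(pm1, NO_MIN_AREA) == "positive"
        if any(r.touches_temporal_disc for r in extract_abnormal_regions(pm0, NO_MIN_AREA)):
            assert any(r.touches_temporal_disc for r in extract_abnormal_regions(pm1, NO_MIN_AREA))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_midline_positive_implies_necessary_condition(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros(TOY_SHAPE, dtype=bool)
        r, c = rng.integers(0, 40), rng.integers(0, 60)
        mask[r : r + rng.integers(3, 30), c : c + rng.integers(3, 36)] = True
        pmap = make_toy_pmap(mask)
        if vertical_midline_rule(pmap, NO_MIN_AREA) == "positive":
            regions = extract_abnormal_regions(pmap, NO_MIN_AREA)
            assert any(r.touches_temporal_disc for r in regions)

    def test_rule_outcomes_mirror_invariant(self):
        """An eye and its OS mirror give identical rule outcomes."""
        from rnfllab.normative import compute_pmap, fit_normative_model

        from conftest import SMALL_PIXEL, SMALL_SHAPE, constant_map

        anatomy = EyeAnatomy()
        defect = DefectSpec(kind="arcuate", wedge_center_angle=70, wedge_width=50,
                            depth_fraction=0.8, severity_label="AG")
        refs = [
            constant_map(0.0, shape=SMALL_SHAPE, pixel_size=SMALL_PIXEL, age=40.0 + i)
            for i in range(25)
        ]
        for i, m in enumerate(refs):
            m.values = synthesize_thickness_map(
                EyeAnatomy(age=40.0 + i), noise_sd=1.0, seed=i,
                shape=SMALL_SHAPE, pixel_size=SMALL_PIXEL,
            ).values
            m.anatomy = EyeAnatomy(age=40.0 + i)
        model = fit_normative_model(refs)
        outcomes = []
        for an in (anatomy, anatomy.mirrored()):
            tmap = synthesize_thickness_map(an, defect, noise_sd=0.0,
                                            shape=SMALL_SHAPE, pixel_size=SMALL_PIXEL)
            pmap = compute_pmap(tmap, model)
            regions = extract_abnormal_regions(pmap)
            outcomes.append(
                (
                    len(regions),
                    any(r.touches_temporal_disc for r in regions),
                    vertical_midline_rule(pmap),
                    classify_artifact_type(regions, pmap),
                )
            )
        assert outcomes[0] == outcomes[1]
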