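"""Geodesic cell areas, per-class areas, percent change, transitions, patches."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import ginkgosdm as g
from ginkgosdm.change import compare_scenarios, patch_stats, transition_map
from ginkgosdm.grid import CLASS_CODES, CategoryGrid, GridGeoref


def _cat(codes, origin_lat=None, cell_size=2.5 / 60.0, mask=None):
    codes = np.asarray(codes, dtype=np.int16)
    n_rows, n_cols = codes.shape
    if origin_lat is None:
        origin_lat = n_rows * cell_size / 2.0  # centered on the equator
    georef = GridGeoref(n_rows=n_rows, n_cols=n_cols, origin_lon=0.0,
                        origin_lat=origin_lat, cell_size=cell_size)
    if mask is None:
        mask = np.ones(codes.shape, dtype=bool)
    return CategoryGrid(georef=georef, codes=codes, mask=mask)


class TestCellArea:
    def test_equatorial_arcminute_cell(self):
        """2.5' cell on the equator: 21.47 km^2 from the band formula."""
        assert g.cell_area_km2(0.0, 2.5 / 60.0) == pytest.approx(21.47, abs=0.01)

    def test_cosine_scaling_at_60_degrees(self):
        ratio = g.cell_area_km2(60.0, 2.5 / 60.0) / g.cell_area_km2(0.0, 2.5 / 60.0)
        assert ratio == pytest.approx(math.cos(math.radians(60)), abs=0.002)

    def test_area_decreases_with_latitude(self):
        lats = np.arange(0.0, 89.0, 5.0)
        areas = [g.cell_area_km2(lat, 0.5) for lat in lats]
        assert all(a > b for a, b in zip(areas, areas[1:]))

    def test_pole_crossing_rejected(self):
        with pytest.raises(ValueError, match="pole"):
            g.cell_area_km2(89.999, 0.5)


class TestClassAreas:
    def test_single_class_carries_everything(self):
        cat = _cat(np.full((10, 10), CLASS_CODES["low"]))
        areas = g.class_areas(cat)
        assert areas["low"] > 0
        assert all(areas[c] == 0.0 for c in g.CLASS_NAMES if c != "low")

    def test_sum_over_classes_conserves_total(self):
        rng = np.random.default_rng(13)
        cat = _cat(rng.integers(0, 6, size=(20, 20)))
        areas = g.class_areas(cat)
        total = sum(
            g.cell_area_km2(lat, cat.georef.cell_size) * cat.georef.n_cols
            for lat in cat.georef.row_center_lats()) / 1e4
        assert sum(areas.values()) == pytest.approx(total, abs=1e-9)

    def test_25_excellent_cells_at_equator(self):
        """25 cells x 21.47 km^2 = 0.0537 x 10^4 km^2 before rounding."""
        codes = np.zeros((10, 10), dtype=int)
        codes[:5, :5] = CLASS_CODES["excellent"]
        cat = _cat(codes)
        areas = g.class_areas(cat)
        assert areas["excellent"] == pytest.approx(0.0537, abs=0.0005)

    def test_longitude_translation_invariance(self):
        rng = np.random.default_rng(14)
        codes = rng.integers(0, 6, size=(8, 8))
        a = g.class_areas(_cat(codes))
        shifted = _cat(codes)
        moved = CategoryGrid(
            georef=GridGeoref(n_rows=8, n_cols=8, origin_lon=120.0,
                              origin_lat=shifted.georef.origin_lat,
                              cell_size=shifted.georef.cell_size),
            codes=shifted.codes, mask=shifted.mask)
        b = g.class_areas(moved)
        for name in g.CLASS_NAMES:
            assert a[name] == pytest.approx(b[name], rel=1e-12)


class TestPercentChange:
    @pytest.mark.parametrize("current,future,expected", [
        (16.5, 15.5, -6.1),   # excellent row, envelope model
        (44.3, 45.4, 2.5),
        (44.0, 44.3, 0.7),
        (41.4, 43.8, 5.8),
        (116.3, 119.9, 3.1),
        (697.5, 691.1, -0.9),
        (75.8, 71.7, -5.4),   # similarity model columns
        (114.1, 113.3, -0.7),
        (43.9, 49.1, 11.8),
        (27.5, 32.3, 17.5),
        (24.8, 27.4, 10.5),
        (673.9, 666.2, -1.1),
    ])
    def test_area_change_table(self, current, future, expected):
        assert g.percent_change(current, future) == expected

    def test_identity_is_zero(self):
        assert g.percent_change(12.3, 12.3) == 0.0

    def test_new_class_marker(self):
        assert math.isnan(g.percent_change(0.0, 5.0))
        assert g.percent_change(0.0, 0.0) == 0.0


class TestTransitionMap:
    def test_identical_grids(self):
        codes = np.zeros((5, 5), dtype=int)
        codes[1:3, 1:3] = CLASS_CODES["excellent"]
        cat = _cat(codes)
        _, counts = transition_map(cat, cat)
        assert counts == {"retained": 4, "lost": 0, "new": 0}

    def test_disjoint_focal_sets(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[0, 0] = CLASS_CODES["excellent"]
        b[3, 3] = CLASS_CODES["excellent"]
        _, counts = transition_map(_cat(a), _cat(b))
        assert counts == {"retained": 0, "lost": 1, "new": 1}

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(cur=hnp.arrays(np.int16, (6, 6), elements=st.integers(0, 5)),
           fut=hnp.arrays(np.int16, (6, 6), elements=st.integers(0, 5)))
    def test_conservation_and_antisymmetry(self, cur, fut):
        c, f = _cat(cur), _cat(fut)
        _, counts = transition_map(c, f)
        n_cur = int((cur == CLASS_CODES["excellent"]).sum())
        n_fut = int((fut == CLASS_CODES["excellent"]).sum())
        assert counts["retained"] + counts["lost"] == n_cur
        assert counts["retained"] + counts["new"] == n_fut
        _, swapped = transition_map(f, c)
        assert swapped["lost"] == counts["new"]
        assert swapped["new"] == counts["lost"]
        assert swapped["retained"] == counts["retained"]

    def test_georeference_mismatch_rejected(self):
        a = _cat(np.zeros((4, 4), dtype=int))
        b = _cat(np.zeros((4, 4), dtype=int), origin_lat=50.0)
        from ginkgosdm.grid import GeoreferenceError
        with pytest.raises(GeoreferenceError, match="mismatch"):
            transition_map(a, b)


class TestPatchStats:
    def test_solid_rectangle_is_one_patch(self):
        codes = np.zeros((6, 6), dtype=int)
        codes[1:4, 2:5] = CLASS_CODES["excellent"]
        stats = patch_stats(_cat(codes))
        assert stats.as_tuple() == (1, 9.0, 9)

    def test_diagonal_cells_split_under_4_connectivity(self):
        codes = np.zeros((3, 3), dtype=int)
        codes[0, 0] = codes[1, 1] = CLASS_CODES["excellent"]
        assert patch_stats(_cat(codes)).n_patches == 2
        assert patch_stats(_cat(codes), connectivity=8).n_patches == 1

    def test_three_isolated_cells(self):
        codes = np.zeros((5, 5), dtype=int)
        for r, c in [(0, 0), (2, 2), (4, 4)]:
            codes[r, c] = CLASS_CODES["excellent"]
        assert patch_stats(_cat(codes)).as_tuple() == (3, 1.0, 1)

    def test_empty_class(self):
        assert patch_stats(_cat(np.zeros((3, 3), dtype=int))).as_tuple() == (0, 0.0, 0)


class TestCompareScenarios:
    def test_identical_grids_zero_change_everywhere(self):
        rng = np.random.default_rng(15)
        cat = _cat(rng.integers(0, 6, size=(12, 12)))
        report = compare_scenarios(cat, cat, model="bioclim")
        for name, change in report.percent_changes.items():
            if report.current_areas[name] > 0:
                assert change == 0.0
        assert report.lost_cells == report.new_cells == 0

    def test_transition_area_consistency(self):
        rng = np.random.default_rng(16)
        cur = _cat(rng.integers(0, 6, size=(12, 12)))
        fut = _cat(rng.integers(0, 6, size=(12, 12)))
        report = compare_scenarios(cur, fut, model="domain", decimals=None)
        assert report.retained_area + report.lost_area == pytest.approx(
            g.class_areas(cur)["excellent"], abs=1e-9)
        assert report.retained_area + report.new_area == pytest.approx(
            g.class_areas(fut)["excellent"], abs=1e-9)
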