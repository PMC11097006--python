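"""Scenario comparison: per-class geodesic areas, percent change,
retained/lost/new transitions for a focal class, and patch fragmentation.

Cell areas are computed on the authalic sphere (R = 6371.0072 km) from the
spherical-band formula, so class areas honestly shrink toward the poles.
Land/sea masking is whatever nodata mask the grids carry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._util import round_half_away
from .grid import (CLASS_CODES, CLASS_NAMES, CategoryGrid, GeoreferenceError,
                   GridGeoref)

AUTHALIC_RADIUS_KM = 6371.0072

TRANSITION_CODES = {"other": 0, "retained": 1, "lost": 2, "new": 3}

#: 4-connectivity structuring element for patch labelling
FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


def cell_area_km2(lat_center: float, cell_size: float) -> float:
    """Area of a cell_size x cell_size degree cell centered at lat_center.

    Spherical band: R^2 * dlambda * (sin(phi_top) - sin(phi_bottom)).
    """
    if abs(lat_center) > 90:
        raise ValueError(f"latitude {lat_center} out of range")
    half = cell_size / 2.0
    if lat_center + half > 90 + 1e-12 or lat_center - half < -90 - 1e-12:
        raise ValueError(
            f"cell centered at {lat_center} with size {cell_size} crosses a pole"
        )
    dlon = math.radians(cell_size)
    top = math.radians(min(lat_center + half, 90.0))
    bottom = math.radians(max(lat_center - half, -90.0))
    return AUTHALIC_RADIUS_KM ** 2 * dlon * (math.sin(top) - math.sin(bottom))


def _row_areas(georef: GridGeoref) -> np.ndarray:
    return np.array([
        cell_area_km2(lat, georef.cell_size)
        for lat in georef.row_center_lats()
    ])


def class_areas(cat: CategoryGrid, *, decimals: int | None = None
                ) -> dict[str, float]:
    """Per-class area in units of 10^4 km^2; absent classes report 0.0."""
    row_areas = _row_areas(cat.georef)
    areas: dict[str, float] = {}
    for name in cat.legend:
        m = cat.class_mask(name)
        total = float((row_areas[:, None] * m).sum()) / 1e4
        areas[name] = round_half_away(total, decimals) if decimals is not None else total
    return areas


def percent_change(current_area: float, future_area: float) -> float:
    """100 * (future - current) / current, half-away-from-zero, one decimal.

    A class absent now but present in the future has no defined percent
    change; NaN is returned as the "new class" marker.
    """
    if current_area < 0 or future_area < 0:
        raise ValueError("areas must be non-negative")
    if current_area == 0:
        return math.nan if future_area > 0 else 0.0
    return round_half_away(100.0 * (future_area - current_area) / current_area, 1)


@dataclass
class PatchStats:
    n_patches: int
    mean_patch_cells: float
    max_patch_cells: int

    def as_tuple(self) -> tuple[int, float, int]:
        return (self.n_patches, self.mean_patch_cells, self.max_patch_cells)


def patch_stats(cat: CategoryGrid, focal_class: str = "excellent",
                connectivity: int = 4) -> PatchStats:
    """Connected-component statistics of the focal class (4-connectivity)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = FOUR_CONNECTED if connectivity == 4 else EIGHT_CONNECTED
    mask = cat.class_mask(focal_class)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return PatchStats(0, 0.0, 0)
    sizes = np.bincount(labels.ravel())[1:]
    return PatchStats(int(n), float(sizes.mean()), int(sizes.max()))


@dataclass
class ChangeReport:
    """Scenario-change accounting for one model."""

    model: str
    focal_class: str
    current_areas: dict[str, float]           # 10^4 km^2
    future_areas: dict[str, float]
    percent_changes: dict[str, float]
    retained_cells: int
    lost_cells: int
    new_cells: int
    retained_area: float                       # 10^4 km^2
    lost_area: float
    new_area: float
    current_patches: PatchStats
    future_patches: PatchStats

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "focal_class": self.focal_class,
            "current_areas_1e4km2": self.current_areas,
            "future_areas_1e4km2": self.future_areas,
            "percent_changes": {
                k: (None if isinstance(v, float) and math.isnan(v) else v)
                for k, v in self.percent_changes.items()
            },
            "transitions": {
                "retained_cells": self.retained_cells,
                "lost_cells": self.lost_cells,
                "new_cells": self.new_cells,
                "retained_area_1e4km2": self.retained_area,
                "lost_area_1e4km2": self.lost_area,
                "new_area_1e4km2": self.new_area,
            },
            "patches": {
                "current": self.current_patches.as_tuple(),
                "future": self.future_patches.as_tuple(),
            },
        }
        return out

    def to_table(self) -> pd.DataFrame:
        """Table shaped like a per-class area/change summary."""
        rows = []
        for name in reversed(CLASS_NAMES):  # excellent first, like the table
            rows.append({
                "class": name,
                "current": self.current_areas[name],
                "future": self.future_areas[name],
                "change_pct": self.percent_changes[name],
            })
        return pd.DataFrame(rows)


def transition_map(current: CategoryGrid, future: CategoryGrid,
                   focal_class: str = "excellent"
                   ) -> tuple[np.ndarray, dict[str, int]]:
    """Grid over {other, retained, lost, new} for the focal class.

    retained = focal in both scenarios; lost = focal only now; new = focal
    only in the future.
    """
    if current.georef != future.georef:
        raise GeoreferenceError(
            f"georeference mismatch between scenarios: "
            f"{current.georef} vs {future.georef}"
        )
    if not np.array_equal(current.mask, future.mask):
        raise GeoreferenceError("nodata masks differ between scenarios")
    cur = current.class_mask(focal_class)
    fut = future.class_mask(focal_class)
    grid = np.full(cur.shape, TRANSITION_CODES["other"], dtype=np.int16)
    grid[cur & fut] = TRANSITION_CODES["retained"]
    grid[cur & ~fut] = TRANSITION_CODES["lost"]
    grid[~cur & fut] = TRANSITION_CODES["new"]
    counts = {
        "retained": int(np.count_nonzero(grid == TRANSITION_CODES["retained"])),
        "lost": int(np.count_nonzero(grid == TRANSITION_CODES["lost"])),
        "new": int(np.count_nonzero(grid == TRANSITION_CODES["new"])),
    }
    return grid, counts


def compare_scenarios(current: CategoryGrid, future: CategoryGrid,
                      model: str, focal_class: str = "excellent",
                      decimals: int | None = 1) -> ChangeReport:
    """Full change accounting between two classified scenarios."""
    cur_areas_raw = class_areas(current)
    fut_areas_raw = class_areas(future)
    changes = {
        name: percent_change(cur_areas_raw[name], fut_areas_raw[name])
        for name in current.legend
    }
    grid, counts = transition_map(current, future, focal_class)
    row_areas = _row_areas(current.georef)

    def _area(code_name: str) -> float:
        m = grid == TRANSITION_CODES[code_name]
        return float((row_areas[:, None] * m).sum()) / 1e4

    rnd = (lambda v: round_half_away(v, decimals)) if decimals is not None else (lambda v: v)
    return ChangeReport(
        model=model,
        focal_class=focal_class,
        current_areas={k: rnd(v) for k, v in cur_areas_raw.items()},
        future_areas={k: rnd(v) for k, v in fut_areas_raw.items()},
        percent_changes=changes,
        retained_cells=counts["retained"],
        lost_cells=counts["lost"],
        new_cells=counts["new"],
        retained_area=rnd(_area("retained")),
        lost_area=rnd(_area("lost")),
        new_area=rnd(_area("new")),
        current_patches=patch_stats(current, focal_class),
        future_patches=patch_stats(future, focal_class),
    )
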