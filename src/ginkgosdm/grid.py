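"""Georeferenced raster grids: the in-memory containers for climate stacks,
suitability surfaces and category maps, plus ESRI ASCII grid I/O.

All grids share a north-up convention: row 0 is the northernmost row and the
georeference origin is the north-west corner of the raster. Coordinates are
WGS84 decimal degrees throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0

#: fixed category code order used in every output
CLASS_NAMES = ("unsuitable", "low", "medium", "high", "very_high", "excellent")
CLASS_CODES = {name: code for code, name in enumerate(CLASS_NAMES)}


class GeoreferenceError(ValueError):
    """Raised when grids with incompatible georeferences are combined."""


@dataclass(frozen=True)
class GridGeoref:
    """Regular lon/lat grid geometry anchored at the north-west corner."""

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lon_max(self) -> float:
        return self.origin_lon + self.n_cols * self.cell_size

    @property
    def lat_min(self) -> float:
        return self.origin_lat - self.n_rows * self.cell_size

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.origin_lon <= lon < self.lon_max
            and self.lat_min < lat <= self.origin_lat
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Return (row, col) of the cell containing a point.

        Points on the western/northern edge of a cell belong to that cell;
        points outside the extent raise ``GeoreferenceError``.
        """
        if not self.contains(lon, lat):
            raise GeoreferenceError(
                f"point ({lon}, {lat}) outside grid extent "
                f"[{self.origin_lon}, {self.lon_max}] x "
                f"[{self.lat_min}, {self.origin_lat}]"
            )
        col = int(math.floor((lon - self.origin_lon) / self.cell_size))
        row = int(math.floor((self.origin_lat - lat) / self.cell_size))
        # guard against float round-off on the extreme edges
        col = min(col, self.n_cols - 1)
        row = min(row, self.n_rows - 1)
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def row_center_lats(self) -> np.ndarray:
        rows = np.arange(self.n_rows)
        return self.origin_lat - (rows + 0.5) * self.cell_size


def _check_same_georef(a: GridGeoref, b: GridGeoref) -> None:
    if a != b:
        raise GeoreferenceError(f"georeference mismatch: {a} vs {b}")


@dataclass
class ClimateStack:
    """Multi-layer bioclimatic raster stack for one climate scenario.

    ``layers`` maps variable name -> 2D float array (row 0 = north);
    ``mask`` is True on valid (non-nodata) cells and is shared by all layers.
    """

    georef: GridGeoref
    layers: dict[str, np.ndarray]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack must hold at least one layer")
        for name, arr in self.layers.items():
            if arr.shape != self.georef.shape:
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} does not match "
                    f"georeference shape {self.georef.shape}"
                )
        if self.mask is None:
            self.mask = np.ones(self.georef.shape, dtype=bool)
        elif self.mask.shape != self.georef.shape:
            raise ValueError("mask shape does not match georeference")

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    def values_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> dict[str, np.ndarray]:
        return {name: arr[rows, cols] for name, arr in self.layers.items()}

    def as_matrix(self, variables: list[str] | None = None) -> np.ndarray:
        """Valid cells as an (n_valid, n_variables) matrix, row-major order."""
        variables = variables or self.variables
        return np.column_stack([self.layers[v][self.mask] for v in variables])

    def copy(self) -> "ClimateStack":
        return ClimateStack(
            georef=self.georef,
            layers={k: v.copy() for k, v in self.layers.items()},
            mask=self.mask.copy(),
        )


@dataclass
class SuitabilityGrid:
    """Continuous model score per cell.

    BIOCLIM scores live in [0, 50]; DOMAIN similarities are <= 100 and may be
    negative. ``model`` tags which classification scheme applies.
    """

    georef: GridGeoref
    scores: np.ndarray
    mask: np.ndarray
    model: str  # "bioclim" | "domain"

    def __post_init__(self) -> None:
        if self.model not in ("bioclim", "domain"):
            raise ValueError(f"unknown model tag {self.model!r}")
        if self.scores.shape != self.georef.shape:
            raise ValueError("score array shape does not match georeference")


@dataclass
class CategoryGrid:
    """Per-cell suitability class, coded 0 (unsuitable) .. 5 (excellent)."""

    georef: GridGeoref
    codes: np.ndarray  # int array; value only meaningful where mask is True
    mask: np.ndarray
    legend: tuple[str, ...] = CLASS_NAMES

    def class_mask(self, name: str) -> np.ndarray:
        return self.mask & (self.codes == CLASS_CODES[name])

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.class_mask(name)))
            for name in self.legend
        }


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (one file per layer; header then rows north to south)

def write_ascii_grid(path: str | Path, array: np.ndarray, georef: GridGeoref,
                     mask: np.ndarray | None = None, nodata: float = NODATA,
                     fmt: str = "%.6g") -> None:
    path = Path(path)
    data = np.asarray(array, dtype=float).copy()
    if mask is not None:
        data[~mask] = nodata
    header = (
        f"ncols {georef.n_cols}\n"
        f"nrows {georef.n_rows}\n"
        f"xllcorner {georef.origin_lon!r}\n"
        f"yllcorner {georef.lat_min!r}\n"
        f"cellsize {georef.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridGeoref, np.ndarray]:
    """Read an ESRI ASCII grid; returns (array, georef, mask)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"):
                header[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    for required in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if required not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {required}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: data shape {data.shape} does not match header "
            f"({n_rows}, {n_cols})"
        )
    cell = header["cellsize"]
    georef = GridGeoref(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + n_rows * cell,
        cell_size=cell,
    )
    nodata = header.get("nodata_value", NODATA)
    mask = data != nodata
    return data, georef, mask


def write_stack(directory: str | Path, stack: ClimateStack) -> list[Path]:
    """Write one .asc file per layer into a directory; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in stack.layers.items():
        p = directory / f"{name}.asc"
        write_ascii_grid(p, arr, stack.georef, mask=stack.mask)
        paths.append(p)
    return paths


def read_stack(directory: str | Path, variables: list[str] | None = None) -> ClimateStack:
    """Read a stack from a directory of .asc files (one per variable)."""
    directory = Path(directory)
    if variables is None:
        variables = sorted(p.stem for p in directory.glob("*.asc"))
    if not variables:
        raise ValueError(f"no .asc layers found in {directory}")
    layers: dict[str, np.ndarray] = {}
    georef = None
    mask = None
    for name in variables:
        arr, g, m = read_ascii_grid(directory / f"{name}.asc")
        if georef is None:
            georef, mask = g, m
        else:
            _check_same_georef(georef, g)
            mask &= m
        layers[name] = arr
    return ClimateStack(georef=georef, layers=layers, mask=mask)
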