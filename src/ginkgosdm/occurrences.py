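"""Presence-record handling: read, validate, thin, split and summarize.

Records are longitude/latitude points in WGS84 decimal degrees with optional
elevation (metres) and an optional admin label. Thinning keeps at most one
record per raster cell — the scriptable counterpart of de-duplicating records
"at the county level" when no administrative polygons are available.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import round_half_away
from .grid import GridGeoref

#: altitudinal class labels and lower-inclusive bin edges in metres
ALTITUDE_CLASSES = ("low", "mid", "mid_high", "high")
ALTITUDE_EDGES = (800.0, 1600.0, 2400.0)


class SchemaError(ValueError):
    """Raised when an occurrence table violates its column/uniqueness schema."""


@dataclass
class OccurrenceTable:
    """Cleaned presence records plus provenance counts.

    ``frame`` always has columns id, lon, lat; elevation and label are
    optional, and synthetic records may carry extra per-variable columns with
    the environmental values of their generating cell.
    """

    frame: pd.DataFrame
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("id", "lon", "lat"):
            if col not in self.frame.columns:
                raise SchemaError(f"occurrence table missing column {col!r}")
        ids = self.frame["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SchemaError(f"duplicated occurrence id {dup!r}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> list[str]:
        return list(self.frame["id"])

    def has_elevation(self) -> bool:
        return "elevation" in self.frame.columns and self.frame["elevation"].notna().any()


def read_occurrences(source: str | Path | io.TextIOBase, *, sep: str | None = None,
                     lon_col: str = "lon", lat_col: str = "lat",
                     elevation_col: str = "elevation",
                     label_col: str = "label", id_col: str = "id") -> OccurrenceTable:
    """Read a delimited text table of presence records.

    Rows with unparsable or out-of-range coordinates are dropped and counted
    in provenance; surviving rows keep their input order. Comma and tab
    dialects are auto-detected unless ``sep`` is given.
    """
    if sep is None:
        sep = None  # pandas python engine sniffs comma vs tab
        raw = pd.read_csv(source, sep=None, engine="python", dtype=str)
    else:
        raw = pd.read_csv(source, sep=sep, dtype=str)
    missing = [c for c in (lon_col, lat_col) if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    n_raw = len(raw)
    lon = pd.to_numeric(raw[lon_col], errors="coerce")
    lat = pd.to_numeric(raw[lat_col], errors="coerce")
    valid = (
        lon.notna() & lat.notna()
        & (lon >= -180) & (lon <= 180) & (lat >= -90) & (lat <= 90)
    )
    kept = raw[valid]
    frame = pd.DataFrame({
        "id": (kept[id_col] if id_col in kept.columns
               else [f"r{i:05d}" for i in kept.index]),
        "lon": lon[valid].astype(float),
        "lat": lat[valid].astype(float),
    })
    if elevation_col in kept.columns:
        elev = pd.to_numeric(kept[elevation_col], errors="coerce")
        elev[~np.isfinite(elev)] = np.nan
        frame["elevation"] = elev
    if label_col in kept.columns:
        frame["label"] = kept[label_col]
    return OccurrenceTable(
        frame=frame,
        provenance={"raw": n_raw, "rejected": int(n_raw - valid.sum()),
                    "deduplicated": 0},
    )


def write_occurrences(occ: OccurrenceTable, path: str | Path, sep: str = ",") -> None:
    occ.frame.to_csv(path, sep=sep, index=False)


def thin_to_cells(occ: OccurrenceTable, georef: GridGeoref) -> OccurrenceTable:
    """Keep at most one record per grid cell (first in input order).

    All points must fall inside the grid extent; an outside point is an error
    rather than a silent drop, since it signals a projection or extent bug.
    """
    seen: set[tuple[int, int]] = set()
    keep_rows: list[int] = []
    for i, rec in occ.frame.iterrows():
        try:
            cell = georef.cell_of(float(rec["lon"]), float(rec["lat"]))
        except ValueError as exc:
            raise ValueError(
                f"occurrence {rec['id']!r} at ({rec['lon']}, {rec['lat']}) "
                f"is outside the grid extent"
            ) from exc
        if cell not in seen:
            seen.add(cell)
            keep_rows.append(i)
    removed = len(occ) - len(keep_rows)
    provenance = dict(occ.provenance)
    provenance["deduplicated"] = provenance.get("deduplicated", 0) + removed
    return OccurrenceTable(frame=occ.frame.loc[keep_rows], provenance=provenance)


def altitude_class_summary(occ: OccurrenceTable) -> dict[str, float]:
    """Percentage of records per altitudinal class, one decimal.

    Classes are lower-inclusive: low [<800), mid [800, 1600), mid_high
    [1600, 2400), high [2400, inf). Records without elevation are excluded
    from the denominator.
    """
    if "elevation" not in occ.frame.columns:
        raise ValueError("no elevation data")
    elev = occ.frame["elevation"].dropna().to_numpy(dtype=float)
    if elev.size == 0:
        raise ValueError("no elevation data")
    counts = [
        int(np.count_nonzero(elev < ALTITUDE_EDGES[0])),
        int(np.count_nonzero((elev >= ALTITUDE_EDGES[0]) & (elev < ALTITUDE_EDGES[1]))),
        int(np.count_nonzero((elev >= ALTITUDE_EDGES[1]) & (elev < ALTITUDE_EDGES[2]))),
        int(np.count_nonzero(elev >= ALTITUDE_EDGES[2])),
    ]
    return {
        name: round_half_away(100.0 * c / elev.size, 1)
        for name, c in zip(ALTITUDE_CLASSES, counts)
    }


def split_train_test(occ: OccurrenceTable, train_fraction: float = 0.7,
                     seed: int = 0) -> tuple[OccurrenceTable, OccurrenceTable]:
    """Random 70/30-style partition into training and validation subsets.

    Train size is n x fraction rounded half away from zero; the partition is
    deterministic for a fixed seed.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(occ)
    if n < 2:
        raise ValueError("too few records to split")
    n_train = int(round_half_away(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = np.sort(order[:n_train])
    test_idx = np.sort(order[n_train:])
    prov = dict(occ.provenance)
    return (
        OccurrenceTable(frame=occ.frame.iloc[train_idx], provenance=prov),
        OccurrenceTable(frame=occ.frame.iloc[test_idx], provenance=prov),
    )


def extent_summary(occ: OccurrenceTable, *, decimals: int | None = None
                   ) -> tuple[float, float, float, float]:
    """Tight bounding box (lon_min, lon_max, lat_min, lat_max) in degrees."""
    if len(occ) == 0:
        raise ValueError("empty occurrence table")
    lon = occ.frame["lon"].to_numpy(dtype=float)
    lat = occ.frame["lat"].to_numpy(dtype=float)
    box = (float(lon.min()), float(lon.max()), float(lat.min()), float(lat.max()))
    if decimals is not None:
        box = tuple(round_half_away(v, decimals) for v in box)  # type: ignore[assignment]
    return box
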