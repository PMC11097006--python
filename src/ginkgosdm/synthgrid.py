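"""Synthetic climate stacks, future-scenario shifts and occurrence samples.

The generator produces spatially smooth, cross-correlated bioclimatic layers
with prescribed per-variable means and standard deviations, plus presence
samples drawn from a known rectangular environmental envelope. Because the
true envelope is known, every downstream stage (envelope fitting, similarity
scoring, AUC validation, scenario change accounting) can be tested for
recovery without any external raster downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ClimateStack, GridGeoref
from .occurrences import OccurrenceTable


class SpecValidationError(ValueError):
    """Raised when a synthetic-data specification is internally inconsistent."""


@dataclass
class SyntheticClimateSpec:
    """Recipe for one synthetic climate stack.

    ``variables`` lists (name, mean, sd) in each variable's native units;
    ``correlation`` is the target cross-variable correlation of the underlying
    standard-normal fields; ``smoothness`` is the radius (in cells) of a
    uniform moving-average smoother applied after cross-correlation, with the
    window truncated at grid edges.
    """

    n_rows: int
    n_cols: int
    origin_lon: float
    origin_lat: float
    cell_size: float
    variables: list[tuple[str, float, float]]
    correlation: np.ndarray | None = None
    smoothness: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise SpecValidationError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise SpecValidationError("cell_size must be positive")
        if not self.variables:
            raise SpecValidationError("at least one variable is required")
        names = [v[0] for v in self.variables]
        if len(set(names)) != len(names):
            raise SpecValidationError("variable names must be unique")
        for name, _mean, sd in self.variables:
            if sd < 0:
                raise SpecValidationError(f"variable {name!r} has negative sd")
        v = len(self.variables)
        if self.correlation is None:
            self.correlation = np.eye(v)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.correlation.shape != (v, v):
            raise SpecValidationError(
                f"correlation matrix shape {self.correlation.shape} "
                f"does not match {v} variables"
            )
        if not np.allclose(self.correlation, self.correlation.T, atol=1e-10):
            raise SpecValidationError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0, atol=1e-10):
            raise SpecValidationError("correlation matrix diagonal must be 1")
        if self.smoothness < 0:
            raise SpecValidationError("smoothness radius must be >= 0")

    @property
    def names(self) -> list[str]:
        return [v[0] for v in self.variables]

    def georef(self) -> GridGeoref:
        return GridGeoref(
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            origin_lon=self.origin_lon,
            origin_lat=self.origin_lat,
            cell_size=self.cell_size,
        )


@dataclass
class TrueEnvelopeSpec:
    """Ground-truth rectangular presence envelope in environmental space.

    Cells whose values fall inside every variable's [lower, upper] interval
    get sampling weight ``inside_weight``; all other cells get
    ``outside_weight`` (0 by default, i.e. strict presence-only support).
    """

    bounds: dict[str, tuple[float, float]]
    inside_weight: float = 1.0
    outside_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.inside_weight <= 0:
            raise SpecValidationError("inside_weight must be positive")
        if self.outside_weight < 0:
            raise SpecValidationError("outside_weight must be non-negative")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise SpecValidationError(
                    f"envelope for {name!r} has lower bound {lo} > upper {hi}"
                )

    def inside(self, stack: ClimateStack) -> np.ndarray:
        """Boolean grid: True where every bounded variable is in its interval."""
        ok = np.ones(stack.georef.shape, dtype=bool)
        for name, (lo, hi) in self.bounds.items():
            layer = stack.layers[name]
            ok &= (layer >= lo) & (layer <= hi)
        return ok


def _correlation_factor(corr: np.ndarray) -> np.ndarray:
    """Square-root factor L with L @ L.T == corr, tolerant of PSD-singular input."""
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() < -1e-8:
        raise SpecValidationError(
            f"correlation matrix is not positive semi-definite "
            f"(minimum eigenvalue {eigval.min():.3g}): {corr.tolist()}"
        )
    return eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))


def _smooth(field: np.ndarray, radius: int) -> np.ndarray:
    """Uniform moving average of radius cells, window truncated at edges.

    The averaged field is rescaled back to unit marginal variance: the input
    cells are spatially independent, so averaging w cells shrinks the sd to
    1/sqrt(w) and multiplying by sqrt(w) restores a standard-normal marginal
    while keeping the induced spatial autocorrelation.
    """
    if radius == 0:
        return field
    size = 2 * radius + 1
    total = ndimage.uniform_filter(field, size=size, mode="constant", cval=0.0)
    weight = ndimage.uniform_filter(
        np.ones_like(field), size=size, mode="constant", cval=0.0
    )
    # total/weight is the truncated-window mean; w = weight * size**2
    return total * size / np.sqrt(weight)


def make_climate_stack(spec: SyntheticClimateSpec) -> ClimateStack:
    """Generate the stack: mean + sd * smoothed, cross-correlated normal field.

    Deterministic for a fixed spec seed. Note the moving-average smoother
    shrinks marginal variance, so per-cell sd equals the spec sd only at
    smoothness 0; spatial structure, not marginal calibration, is the point
    of the smoother.
    """
    rng = np.random.default_rng(spec.seed)
    v = len(spec.variables)
    iid = rng.standard_normal(size=(v, spec.n_rows, spec.n_cols))
    factor = _correlation_factor(spec.correlation)
    correlated = np.einsum("vw,wij->vij", factor, iid)
    layers: dict[str, np.ndarray] = {}
    for k, (name, mean, sd) in enumerate(spec.variables):
        layers[name] = mean + sd * _smooth(correlated[k], spec.smoothness)
    return ClimateStack(georef=spec.georef(), layers=layers)


def make_future_stack(current: ClimateStack, deltas: dict[str, float]) -> ClimateStack:
    """Future scenario = current + per-layer additive shift; mask preserved."""
    unknown = sorted(set(deltas) - set(current.layers))
    if unknown:
        raise KeyError(
            f"unknown variables in deltas: {unknown}; "
            f"valid names: {sorted(current.layers)}"
        )
    future = current.copy()
    for name, delta in deltas.items():
        future.layers[name] = future.layers[name] + float(delta)
    return future


def sample_occurrences(stack: ClimateStack, env: TrueEnvelopeSpec, n: int,
                       seed: int) -> OccurrenceTable:
    """Draw n presence points at cell centers, weight proportional sampling.

    Cells inside the true envelope carry ``inside_weight``, the rest
    ``outside_weight``; nodata cells are never sampled. Each record stores its
    cell's environmental values so tests can verify extraction exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    inside = env.inside(stack)
    weights = np.where(inside, env.inside_weight, env.outside_weight)
    weights = np.where(stack.mask, weights, 0.0)
    flat = weights.ravel()
    total = flat.sum()
    if total <= 0:
        raise ValueError("no habitable cells: all sampling weights are zero")
    n_positive = int(np.count_nonzero(flat))
    if n > n_positive:
        raise ValueError(
            f"cannot draw {n} cells without replacement from "
            f"{n_positive} cells with positive weight"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat.size, size=n, replace=False, p=flat / total)
    rows, cols = np.unravel_index(chosen, stack.georef.shape)
    lons = stack.georef.origin_lon + (cols + 0.5) * stack.georef.cell_size
    lats = stack.georef.origin_lat - (rows + 0.5) * stack.georef.cell_size
    data = {
        "id": [f"occ{i:04d}" for i in range(n)],
        "lon": lons,
        "lat": lats,
    }
    for name, arr in stack.layers.items():
        data[name] = arr[rows, cols]
    frame = pd.DataFrame(data)
    return OccurrenceTable(
        frame=frame,
        provenance={"raw": n, "rejected": 0, "deduplicated": 0},
    )


# ---------------------------------------------------------------------------
# Default synthetic study scenario: the six VIF-selected bioclimatic
# variables, with means and spreads matching the descriptive statistics of
# the occurrence region (bio13 has no printed row; 200 +/- 70 mm is used).

DEFAULT_VARIABLES: list[tuple[str, float, float]] = [
    ("bio6", -1.7, 4.0),     # min temperature of the coldest month, deg C
    ("bio8", 23.6, 2.5),     # mean temperature of the wettest quarter, deg C
    ("bio10", 25.3, 1.9),    # mean temperature of the warmest quarter, deg C
    ("bio11", 3.6, 3.3),     # mean temperature of the coldest quarter, deg C
    ("bio12", 1113.2, 369.4),  # annual precipitation, mm
    ("bio13", 200.0, 70.0),  # precipitation of the wettest month, mm
]

DEFAULT_CORRELATION = np.array([
    # bio6   bio8   bio10  bio11  bio12  bio13
    [1.00, 0.40, 0.30, 0.85, 0.45, 0.30],
    [0.40, 1.00, 0.60, 0.35, 0.25, 0.20],
    [0.30, 0.60, 1.00, 0.30, 0.10, 0.10],
    [0.85, 0.35, 0.30, 1.00, 0.45, 0.30],
    [0.45, 0.25, 0.10, 0.45, 1.00, 0.80],
    [0.30, 0.20, 0.10, 0.30, 0.80, 1.00],
])

#: additive shifts standing in for a doubled-CO2 2100 scenario
DEFAULT_FUTURE_DELTAS: dict[str, float] = {
    "bio6": 3.5, "bio8": 3.2, "bio10": 3.8, "bio11": 3.6,
    "bio12": 90.0, "bio13": 15.0,
}

DEFAULT_SEED = 20240516


def default_spec(seed: int = DEFAULT_SEED, n_rows: int = 120,
                 n_cols: int = 120, smoothness: int = 2) -> SyntheticClimateSpec:
    """The default synthetic scenario used by the pipeline and the tests."""
    return SyntheticClimateSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_lon=98.5,
        origin_lat=40.4,
        cell_size=2.5 / 60.0,
        variables=list(DEFAULT_VARIABLES),
        correlation=DEFAULT_CORRELATION.copy(),
        smoothness=smoothness,
        seed=seed,
    )


def default_envelope(width_sd: float = 0.8) -> TrueEnvelopeSpec:
    """Informative true envelope: a +/- ``width_sd``-sd box around each mean."""
    bounds = {
        name: (mean - width_sd * sd, mean + width_sd * sd)
        for name, mean, sd in DEFAULT_VARIABLES
    }
    return TrueEnvelopeSpec(bounds=bounds)


def flat_envelope(stack: ClimateStack) -> TrueEnvelopeSpec:
    """Uninformative envelope spanning each layer's full range (null model)."""
    bounds = {
        name: (float(arr[stack.mask].min()), float(arr[stack.mask].max()))
        for name, arr in stack.layers.items()
    }
    return TrueEnvelopeSpec(bounds=bounds)
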