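"""DOMAIN similarity model.

Each site is scored by its range-standardized Gower similarity to the most
similar training record: the Gower distance to a training point is the mean
over variables of |difference| / training range, and the similarity is
100 * (1 - minimum distance). Identity with any training point gives 100;
values are unbounded below (a site far outside the training cloud can score
deeply negative) and no flooring is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import distance

from .envstats import EnvMatrix
from .grid import CLASS_NAMES, CategoryGrid, ClimateStack, SuitabilityGrid

#: lower band edges of the six-level confidence scheme; lower-inclusive
DOMAIN_BAND_EDGES = (90.0, 92.0, 94.0, 96.0, 98.0)


@dataclass
class DomainReference:
    """Training points plus per-variable ranges (max - min over training)."""

    points: np.ndarray          # (n_train, n_variables), native units
    ranges: np.ndarray          # (n_variables,)
    variables: list[str]

    @property
    def n_train(self) -> int:
        return self.points.shape[0]


def fit_domain(train: EnvMatrix) -> DomainReference:
    if len(train) < 1:
        raise ValueError("DOMAIN needs at least 1 training row")
    points = train.values.to_numpy(dtype=float)
    ranges = points.max(axis=0) - points.min(axis=0)
    return DomainReference(points=points, ranges=ranges,
                           variables=list(train.variables))


def _gower_min_distance(ref: DomainReference, x: np.ndarray) -> np.ndarray:
    """Minimum Gower distance of each row of x to the training points.

    Zero-range variables contribute 0 on an exact match and 1 otherwise —
    the limit of |dx|/r as the training spread collapses.
    """
    n_var = len(ref.variables)
    pos = ref.ranges > 0
    total = np.zeros((x.shape[0], ref.n_train))
    if pos.any():
        xs = x[:, pos] / ref.ranges[pos]
        ts = ref.points[:, pos] / ref.ranges[pos]
        total += distance.cdist(xs, ts, metric="cityblock")
    if (~pos).any():
        mismatch = x[:, ~pos][:, None, :] != ref.points[:, ~pos][None, :, :]
        total += mismatch.sum(axis=2)
    return total.min(axis=1) / n_var


def domain_similarity(ref: DomainReference, x: dict[str, float]) -> float:
    return float(domain_similarity_batch(
        ref, {k: np.asarray([v], dtype=float) for k, v in x.items()})[0])


def domain_similarity_batch(ref: DomainReference,
                            x: dict[str, np.ndarray]) -> np.ndarray:
    missing = [v for v in ref.variables if v not in x]
    if missing:
        raise KeyError(f"missing variables in input: {missing}")
    matrix = np.column_stack([
        np.asarray(x[name], dtype=float) for name in ref.variables
    ])
    return 100.0 * (1.0 - _gower_min_distance(ref, matrix))


def domain_predict_grid(ref: DomainReference, stack: ClimateStack,
                        chunk_cells: int = 20000) -> SuitabilityGrid:
    """Cellwise nearest-training-point similarity; nodata propagates.

    The exact scan over training points is chunked over cells to bound the
    (cells x points) pairwise block held in memory.
    """
    missing = [v for v in ref.variables if v not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing layers: {missing}")
    flat = np.column_stack([
        stack.layers[name].ravel() for name in ref.variables
    ])
    sims = np.empty(flat.shape[0])
    for start in range(0, flat.shape[0], chunk_cells):
        block = flat[start:start + chunk_cells]
        sims[start:start + chunk_cells] = 100.0 * (
            1.0 - _gower_min_distance(ref, block)
        )
    scores = sims.reshape(stack.georef.shape)
    scores = np.where(stack.mask, scores, np.nan)
    return SuitabilityGrid(georef=stack.georef, scores=scores,
                           mask=stack.mask.copy(), model="domain")


def classify_domain_scores(scores: np.ndarray) -> np.ndarray:
    """Map similarities to codes 0-5 with lower-inclusive thresholds:
    <90 unsuitable, [90,92) low, [92,94) medium, [94,96) high,
    [96,98) very_high, >=98 excellent."""
    scores = np.asarray(scores, dtype=float)
    codes = np.zeros(scores.shape, dtype=np.int16)
    for code, edge in enumerate(DOMAIN_BAND_EDGES, start=1):
        codes[scores >= edge] = code
    return codes


def classify_domain(grid: SuitabilityGrid) -> CategoryGrid:
    if grid.model != "domain":
        raise ValueError(
            f"wrong model tag: expected 'domain' scores, got {grid.model!r}"
        )
    codes = classify_domain_scores(np.nan_to_num(grid.scores, nan=-1e9))
    return CategoryGrid(georef=grid.georef, codes=codes, mask=grid.mask.copy(),
                        legend=CLASS_NAMES)
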