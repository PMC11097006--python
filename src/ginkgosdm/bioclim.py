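"""BIOCLIM climatic-envelope model.

A site is scored by the two-tailed percentile position of its environmental
values within the training sample: for each variable the mid-rank percentile
p of the site's value among the training values is folded into the tail score
min(p, 1 - p), and the site score is 100 times the minimum tail score over
variables. The score is therefore in [0, 50], maximal at the training median
of every variable, and exactly 0 whenever any variable falls outside the
range observed in training. This two-tailed percentile index is the one
inferential reconstruction in this package: the classical envelope software
popularized the banding used here (top band ending near 41, below the
theoretical 50, as finite training samples rarely sit exactly at the median)
without printing the index formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envstats import EnvMatrix
from .grid import CLASS_NAMES, CategoryGrid, ClimateStack, SuitabilityGrid

#: upper band edges of the six-level suitability scheme (percent units);
#: score 0 is its own "unsuitable" class, bands are upper-inclusive
BIOCLIM_BAND_EDGES = (2.5, 5.0, 10.0, 20.0)


@dataclass
class BioclimEnvelope:
    """Fitted envelope: sorted training values and range per variable."""

    sorted_values: dict[str, np.ndarray]
    n_train: int

    @property
    def variables(self) -> list[str]:
        return list(self.sorted_values)

    def limits(self, variable: str) -> tuple[float, float]:
        v = self.sorted_values[variable]
        return float(v[0]), float(v[-1])


def fit_bioclim(train: EnvMatrix, min_rows: int = 5) -> BioclimEnvelope:
    """Store the sorted training values of every variable."""
    if len(train) < min_rows:
        raise ValueError(
            f"BIOCLIM needs at least {min_rows} training rows, got {len(train)}"
        )
    sorted_values = {
        name: np.sort(train.values[name].to_numpy(dtype=float))
        for name in train.variables
    }
    return BioclimEnvelope(sorted_values=sorted_values, n_train=len(train))


def _tail_scores(envelope: BioclimEnvelope, name: str, x: np.ndarray) -> np.ndarray:
    """min(p, 1-p) with mid-rank percentile p; -1 flags out-of-envelope."""
    v = envelope.sorted_values[name]
    n = envelope.n_train
    below = np.searchsorted(v, x, side="left")
    upto = np.searchsorted(v, x, side="right")
    p = (below + upto) / (2.0 * n)
    s = np.minimum(p, 1.0 - p)
    out = (x < v[0]) | (x > v[-1])
    return np.where(out, -1.0, s)


def bioclim_score(envelope: BioclimEnvelope, x: dict[str, float]) -> float:
    """Score one site; 100 * min over variables of the tail score, 0 outside."""
    scores = bioclim_score_batch(envelope,
                                 {k: np.asarray([v], dtype=float)
                                  for k, v in x.items()})
    return float(scores[0])


def bioclim_score_batch(envelope: BioclimEnvelope,
                        x: dict[str, np.ndarray]) -> np.ndarray:
    missing = [v for v in envelope.variables if v not in x]
    if missing:
        raise KeyError(f"missing variables in input: {missing}")
    stacked = np.stack([
        _tail_scores(envelope, name, np.asarray(x[name], dtype=float))
        for name in envelope.variables
    ])
    s = stacked.min(axis=0)
    return np.where(s < 0, 0.0, 100.0 * s)


def bioclim_predict_grid(envelope: BioclimEnvelope,
                         stack: ClimateStack) -> SuitabilityGrid:
    """Cellwise envelope score over the stack; nodata propagates."""
    missing = [v for v in envelope.variables if v not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing layers: {missing}")
    x = {name: stack.layers[name].ravel() for name in envelope.variables}
    scores = bioclim_score_batch(envelope, x).reshape(stack.georef.shape)
    scores = np.where(stack.mask, scores, np.nan)
    return SuitabilityGrid(georef=stack.georef, scores=scores,
                           mask=stack.mask.copy(), model="bioclim")


def classify_bioclim_scores(scores: np.ndarray) -> np.ndarray:
    """Map scores to codes 0-5: 0 -> unsuitable; (0, 2.5] -> low;
    (2.5, 5] -> medium; (5, 10] -> high; (10, 20] -> very_high; >20 -> excellent."""
    scores = np.asarray(scores, dtype=float)
    codes = np.zeros(scores.shape, dtype=np.int16)
    codes[scores > 0] = 1
    for code, edge in enumerate(BIOCLIM_BAND_EDGES, start=2):
        codes[scores > edge] = code
    return codes


def classify_bioclim(grid: SuitabilityGrid) -> CategoryGrid:
    if grid.model != "bioclim":
        raise ValueError(
            f"wrong model tag: expected 'bioclim' scores, got {grid.model!r}"
        )
    codes = classify_bioclim_scores(np.nan_to_num(grid.scores, nan=0.0))
    return CategoryGrid(georef=grid.georef, codes=codes, mask=grid.mask.copy(),
                        legend=CLASS_NAMES)
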