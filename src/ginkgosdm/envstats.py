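"""Environmental diagnostics at occurrence points.

Covers raster-value extraction, descriptive statistics of the kind printed
for bioclimatic variables (min/max, mean +/- sd, coefficient of variation,
95% confidence interval), stepwise variance-inflation-factor pruning of
collinear predictors, and principal component analysis of the correlation
matrix to identify the dominant climatic drivers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import round_half_away
from .grid import ClimateStack
from .occurrences import OccurrenceTable

#: VIF assigned when the regression R-squared is numerically 1
VIF_SENTINEL = 1e12


@dataclass
class EnvMatrix:
    """Per-occurrence environmental values (rows = records, cols = variables)."""

    values: pd.DataFrame  # indexed by record id
    n_dropped_nodata: int = 0

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate variable names in environmental matrix")
        if self.values.isna().any().any():
            raise ValueError("environmental matrix contains missing values")

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, variables: list[str]) -> "EnvMatrix":
        missing = [v for v in variables if v not in self.values.columns]
        if missing:
            raise KeyError(f"variables not in matrix: {missing}")
        return EnvMatrix(self.values[variables], self.n_dropped_nodata)


@dataclass
class VifReport:
    """Round-by-round stepwise VIF elimination trace."""

    rounds: list[pd.DataFrame]          # per-round (variable, vif) tables
    kept: list[str]
    dropped: list[tuple[str, float]]    # (variable, VIF at removal), in order
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for i, tbl in enumerate(self.rounds):
            t = tbl.copy()
            t.insert(0, "round", i + 1)
            parts.append(t)
        return pd.concat(parts, ignore_index=True)


@dataclass
class PcaResult:
    eigenvalues: np.ndarray              # descending
    proportion_of_variance: np.ndarray   # percent per component
    loadings: pd.DataFrame               # variables x components, unit columns

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def extract_at_points(stack: ClimateStack, occ: OccurrenceTable) -> EnvMatrix:
    """Value of every layer at the cell containing each occurrence.

    Rows whose cell is nodata in any layer are dropped and counted.
    A point outside the stack extent is an error carrying the record id.
    """
    rows = np.empty(len(occ), dtype=int)
    cols = np.empty(len(occ), dtype=int)
    for i, rec in enumerate(occ.frame.itertuples(index=False)):
        try:
            rows[i], cols[i] = stack.georef.cell_of(float(rec.lon), float(rec.lat))
        except ValueError as exc:
            raise ValueError(
                f"occurrence {rec.id!r} is outside the climate stack extent"
            ) from exc
    valid = stack.mask[rows, cols]
    data = {
        name: arr[rows[valid], cols[valid]]
        for name, arr in stack.layers.items()
    }
    ids = np.asarray(occ.ids, dtype=object)[valid]
    frame = pd.DataFrame(data, index=pd.Index(ids, name="id"))
    return EnvMatrix(values=frame, n_dropped_nodata=int((~valid).sum()))


def descriptive_stats(env: EnvMatrix, *, decimals: int | None = 1) -> pd.DataFrame:
    """Min, max, mean, sample sd, CV% and normal-approximation 95% CI.

    cv = 100 * sd / |mean| (reported as NaN when the mean is exactly zero
    with positive spread); ci95 = mean -/+ 1.96 * sd / sqrt(n). With
    ``decimals`` set, every column is rounded half-away-from-zero to that
    many places, matching the usual reporting style of such tables.
    """
    if len(env) < 2:
        raise ValueError("descriptive statistics need at least 2 rows")
    x = env.values
    n = len(x)
    mean = x.mean()
    sd = x.std(ddof=1)
    half = 1.96 * sd / math.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean.abs()
    cv = cv.where(~((mean == 0) & (sd > 0)), np.nan)
    cv = cv.where(sd > 0, 0.0)
    table = pd.DataFrame({
        "min": x.min(),
        "max": x.max(),
        "mean": mean,
        "sd": sd,
        "cv": cv,
        "ci95_low": mean - half,
        "ci95_high": mean + half,
    })
    if decimals is not None:
        table = table.map(
            lambda v: round_half_away(v, decimals) if np.isfinite(v) else v
        )
    return table


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1 - R^2) of regressing it on the other columns."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    model = sm.OLS(y, sm.add_constant(others, has_constant="add")).fit()
    r2 = float(model.rsquared)
    if r2 >= 1.0 - 1e-12:
        return VIF_SENTINEL
    return 1.0 / (1.0 - r2)


def vif_stepwise(env: EnvMatrix, threshold: float = 5.0) -> VifReport:
    """Greedy stepwise collinearity pruning by variance inflation factor.

    While any variable's VIF is >= threshold, drop the one with the largest
    VIF (ties broken toward the later column) and recompute. Perfectly
    collinear variables get a large finite sentinel VIF rather than inf so
    the loop stays total.
    """
    if len(env.variables) < 3:
        raise ValueError("stepwise VIF needs at least 3 variables")
    if len(env) <= len(env.variables):
        raise ValueError("need more rows than variables for VIF regressions")
    remaining = list(env.variables)
    rounds: list[pd.DataFrame] = []
    dropped: list[tuple[str, float]] = []
    while True:
        X = env.values[remaining].to_numpy(dtype=float)
        vifs = np.array([_vif_one(X, j) for j in range(len(remaining))])
        rounds.append(pd.DataFrame({"variable": remaining, "vif": vifs}))
        if vifs.max() < threshold or len(remaining) == 1:
            break
        # argmax returns the first maximum; ties go to the later column
        worst = int(np.flatnonzero(vifs == vifs.max())[-1])
        dropped.append((remaining[worst], float(vifs[worst])))
        remaining = [v for i, v in enumerate(remaining) if i != worst]
    return VifReport(rounds=rounds, kept=remaining, dropped=dropped,
                     threshold=threshold)


def pca(env: EnvMatrix, standardize: bool = True) -> PcaResult:
    """PCA by eigendecomposition of the correlation (or covariance) matrix.

    The correlation matrix is the default because bioclimatic variables mix
    units (deg C, mm, dimensionless seasonality indices). Loadings are unit
    eigenvectors with the sign convention that each column's largest-magnitude
    entry is positive.
    """
    if len(env.variables) < 2:
        raise ValueError("PCA needs at least 2 variables")
    if len(env) < 3:
        raise ValueError("PCA needs at least 3 rows")
    x = env.values.to_numpy(dtype=float)
    if standardize:
        sds = x.std(axis=0, ddof=1)
        zero = [env.variables[j] for j in np.flatnonzero(sds == 0)]
        if zero:
            raise ValueError(
                f"zero-variance columns cannot be standardized: {zero}"
            )
        matrix = np.corrcoef(x, rowvar=False)
    else:
        matrix = np.cov(x, rowvar=False)
    eigval, eigvec = np.linalg.eigh(matrix)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        col = eigvec[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            eigvec[:, k] = -col
    proportions = 100.0 * eigval / eigval.sum()
    loadings = pd.DataFrame(
        eigvec,
        index=env.variables,
        columns=[f"PC{k + 1}" for k in range(len(eigval))],
    )
    return PcaResult(eigenvalues=eigval, proportion_of_variance=proportions,
                     loadings=loadings)
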