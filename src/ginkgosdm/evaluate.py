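"""Presence-vs-background validation with replicated train/test splits.

Presence-only models have no true absences, so discrimination is measured
against a random background sample of non-presence cells: the AUC is the
probability that a random test presence outscores a random background cell
(rank-based, mid-rank ties). Model runs are replicated over independent
70/30 splits; the replicate score grids are averaged cellwise into the
final suitability surface, and the AUC is reported as mean +/- sd with the
conventional performance band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bioclim import bioclim_predict_grid, fit_bioclim
from .domain import domain_predict_grid, fit_domain
from .envstats import EnvMatrix, extract_at_points
from .grid import ClimateStack, SuitabilityGrid
from .occurrences import OccurrenceTable, split_train_test

#: AUC performance bands, lower-inclusive on each edge
AUC_BANDS = ((0.6, "fail"), (0.7, "bad"), (0.8, "fair"), (0.9, "good"),
             (1.0 + 1e-9, "excellent"))


def auc_band(mean_auc: float) -> str:
    """fail [<0.6), bad [0.6,0.7), fair [0.7,0.8), good [0.8,0.9), excellent [0.9,1]."""
    for edge, label in AUC_BANDS:
        if mean_auc < edge:
            return label
    return "excellent"


@dataclass
class EvalReport:
    aucs: list[float]
    mean_auc: float
    sd_auc: float
    band: str
    n_replicates: int
    background_n: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "aucs": [float(a) for a in self.aucs],
            "mean_auc": float(self.mean_auc),
            "sd_auc": float(self.sd_auc),
            "band": self.band,
            "n_replicates": self.n_replicates,
            "background_n": self.background_n,
            "seed": self.seed,
        }


@dataclass
class ReplicateResult:
    report: EvalReport
    mean_grid: SuitabilityGrid
    mean_future_grid: SuitabilityGrid | None = None
    replicate_grids: list[SuitabilityGrid] = field(default_factory=list)


def sample_background(stack: ClimateStack, exclude: OccurrenceTable, n: int,
                      seed: int) -> EnvMatrix:
    """Uniformly sample n distinct non-nodata, non-presence cells."""
    eligible = stack.mask.copy()
    for rec in exclude.frame.itertuples(index=False):
        row, col = stack.georef.cell_of(float(rec.lon), float(rec.lat))
        eligible[row, col] = False
    flat_idx = np.flatnonzero(eligible.ravel())
    if n > flat_idx.size:
        raise ValueError(
            f"requested {n} background cells but only {flat_idx.size} "
            f"eligible cells exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat_idx, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, stack.georef.shape)
    frame = pd.DataFrame(
        {name: arr[rows, cols] for name, arr in stack.layers.items()},
        index=pd.Index([f"bg{i:05d}" for i in range(n)], name="id"),
    )
    return EnvMatrix(values=frame)


def auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann-Whitney) AUC with mid-rank tie handling."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    u = stats.mannwhitneyu(p, b, alternative="two-sided",
                           method="asymptotic").statistic
    return float(u) / (p.size * b.size)


_FITTERS = {
    "bioclim": (fit_bioclim, bioclim_predict_grid),
    "domain": (fit_domain, domain_predict_grid),
}


def replicate_evaluation(occ: OccurrenceTable, stack: ClimateStack,
                         model: str = "bioclim", k: int = 10,
                         background_n: int | None = None, seed: int = 0,
                         train_fraction: float = 0.7,
                         future_stack: ClimateStack | None = None,
                         keep_replicates: bool = False) -> ReplicateResult:
    """k independent 70/30 splits: fit, score the grid, AUC against background.

    Replicate r derives its randomness from seed + r so each run is
    independently reproducible. The returned grid is the cellwise mean of
    the k replicate score grids (and likewise for the future stack when
    provided, using the same k fitted models).
    """
    if k < 2:
        raise ValueError("need at least 2 replicates")
    if model not in _FITTERS:
        raise ValueError(f"unknown model {model!r}")
    fit, predict = _FITTERS[model]
    aucs: list[float] = []
    grids: list[SuitabilityGrid] = []
    future_sum = None
    score_sum = np.zeros(stack.georef.shape)
    for r in range(k):
        rep_seed = seed + r
        train, test = split_train_test(occ, train_fraction, seed=rep_seed)
        train_env = extract_at_points(stack, train)
        fitted = fit(train_env)
        grid = predict(fitted, stack)
        n_bg = background_n if background_n is not None else 10 * len(test)
        n_eligible = int(stack.mask.sum()) - len(occ)
        n_bg = min(n_bg, n_eligible)
        background = sample_background(stack, occ, n_bg, seed=rep_seed + 10_000)
        if model == "bioclim":
            from .bioclim import bioclim_score_batch as scorer
        else:
            from .domain import domain_similarity_batch as scorer
        test_env = extract_at_points(stack, test)
        p_scores = scorer(fitted, {v: test_env.values[v].to_numpy()
                                   for v in test_env.variables})
        b_scores = scorer(fitted, {v: background.values[v].to_numpy()
                                   for v in background.variables})
        aucs.append(auc(p_scores, b_scores))
        score_sum += np.nan_to_num(grid.scores, nan=0.0)
        if keep_replicates:
            grids.append(grid)
        if future_stack is not None:
            fgrid = predict(fitted, future_stack)
            if future_sum is None:
                future_sum = np.zeros(future_stack.georef.shape)
            future_sum += np.nan_to_num(fgrid.scores, nan=0.0)
    mean_scores = np.where(stack.mask, score_sum / k, np.nan)
    mean_grid = SuitabilityGrid(georef=stack.georef, scores=mean_scores,
                                mask=stack.mask.copy(), model=model)
    mean_future = None
    if future_stack is not None and future_sum is not None:
        mf = np.where(future_stack.mask, future_sum / k, np.nan)
        mean_future = SuitabilityGrid(georef=future_stack.georef, scores=mf,
                                      mask=future_stack.mask.copy(), model=model)
    arr = np.asarray(aucs)
    report = EvalReport(
        aucs=aucs,
        mean_auc=float(arr.mean()),
        sd_auc=float(arr.std(ddof=1)),
        band=auc_band(float(arr.mean())),
        n_replicates=k,
        background_n=int(n_bg),
        seed=seed,
    )
    return ReplicateResult(report=report, mean_grid=mean_grid,
                           mean_future_grid=mean_future,
                           replicate_grids=grids)
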