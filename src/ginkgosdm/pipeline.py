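"""Pipeline orchestration: simulate -> prepare -> select -> fit -> predict ->
classify -> evaluate -> compare, with a JSON run manifest.

Every stage writes plain-text artifacts (CSV tables, JSON reports, ESRI
ASCII rasters) under the configured output directory, and the manifest
records the seed, input hashes and per-stage timings so any output can be
re-derived.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bioclim import classify_bioclim
from .change import compare_scenarios, transition_map
from .domain import classify_domain
from .envstats import descriptive_stats, extract_at_points, pca, vif_stepwise
from .evaluate import replicate_evaluation
from .grid import ClimateStack, write_ascii_grid, write_stack, read_stack
from .occurrences import (OccurrenceTable, altitude_class_summary,
                          extent_summary, read_occurrences, thin_to_cells,
                          write_occurrences)
from .synthgrid import (DEFAULT_FUTURE_DELTAS, SyntheticClimateSpec,
                        TrueEnvelopeSpec, default_envelope, default_spec,
                        make_climate_stack, make_future_stack,
                        sample_occurrences)


class ConfigError(ValueError):
    """Raised when a pipeline configuration is invalid."""


@dataclass
class PipelineConfig:
    occurrences: str | Path
    current_stack: str | Path
    out_dir: str | Path
    future_stack: str | Path | None = None
    models: list[str] = field(default_factory=lambda: ["bioclim", "domain"])
    variables: list[str] | None = None
    vif_threshold: float = 5.0
    train_fraction: float = 0.7
    replicates: int = 10
    background_n: int | None = None
    seed: int = 0
    focal_class: str = "excellent"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.replicates < 2:
            raise ConfigError("replicates must be >= 2")
        bad = [m for m in self.models if m not in ("bioclim", "domain")]
        if bad:
            raise ConfigError(f"unknown models: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"bad config file {path}: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _hash_inputs(config: PipelineConfig) -> dict[str, str]:
    hashes: dict[str, str] = {}
    occ = Path(config.occurrences)
    if occ.is_file():
        hashes[str(occ)] = _sha256(occ)
    for stack_dir in (config.current_stack, config.future_stack):
        if stack_dir is None:
            continue
        for p in sorted(Path(stack_dir).glob("*.asc")):
            hashes[str(p)] = _sha256(p)
    return hashes


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in vars(config).items()},
        "input_hashes": _hash_inputs(config),
        "stages": {},
        "outputs": [],
        "notes": [],
    }
    classify = {"bioclim": classify_bioclim, "domain": classify_domain}

    def _stage(name: str):
        manifest["stages"][name] = {"started": time.time()}
        return time.perf_counter()

    def _done(name: str, t0: float) -> None:
        manifest["stages"][name]["seconds"] = round(time.perf_counter() - t0, 3)

    def _emit(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(out)))

    try:
        # ---- prepare ----------------------------------------------------
        t0 = _stage("prepare")
        current = read_stack(config.current_stack, config.variables)
        occ = read_occurrences(config.occurrences)
        occ = thin_to_cells(occ, current.georef)
        write_occurrences(occ, out / "occurrences_thinned.csv")
        _emit(out / "occurrences_thinned.csv")
        prepare_summary = {
            "n_records": len(occ),
            "provenance": occ.provenance,
            "extent": extent_summary(occ),
        }
        if occ.has_elevation():
            prepare_summary["altitude_classes_pct"] = altitude_class_summary(occ)
        (out / "prepare_summary.json").write_text(
            json.dumps(prepare_summary, indent=2))
        _emit(out / "prepare_summary.json")
        _done("prepare", t0)

        # ---- variable selection -----------------------------------------
        t0 = _stage("select")
        env = extract_at_points(current, occ)
        stats_table = descriptive_stats(env)
        stats_table.to_csv(out / "descriptive_stats.csv")
        _emit(out / "descriptive_stats.csv")
        vif = vif_stepwise(env, threshold=config.vif_threshold)
        vif.to_frame().to_csv(out / "vif_report.csv", index=False)
        (out / "vif_report.json").write_text(json.dumps({
            "threshold": vif.threshold,
            "kept": vif.kept,
            "dropped": [{"variable": v, "vif": x} for v, x in vif.dropped],
        }, indent=2))
        _emit(out / "vif_report.csv")
        _emit(out / "vif_report.json")
        env_kept = env.subset(vif.kept)
        pca_result = pca(env_kept)
        (out / "pca_report.json").write_text(json.dumps({
            "eigenvalues": pca_result.eigenvalues.tolist(),
            "proportion_of_variance_pct": pca_result.proportion_of_variance.tolist(),
            "loadings": pca_result.loadings.round(6).to_dict(),
        }, indent=2))
        _emit(out / "pca_report.json")
        _done("select", t0)

        # ---- fit / predict / evaluate per model --------------------------
        future = None
        if config.future_stack is not None:
            future = read_stack(config.future_stack, config.variables)
        else:
            manifest["notes"].append("no scenario comparison: future stack not configured")
        current_kept = ClimateStack(
            georef=current.georef,
            layers={v: current.layers[v] for v in vif.kept},
            mask=current.mask,
        )
        future_kept = None
        if future is not None:
            future_kept = ClimateStack(
                georef=future.georef,
                layers={v: future.layers[v] for v in vif.kept},
                mask=future.mask,
            )
        categories: dict[str, dict[str, object]] = {}
        for model in config.models:
            t0 = _stage(f"model_{model}")
            result = replicate_evaluation(
                occ, current_kept, model=model, k=config.replicates,
                background_n=config.background_n, seed=config.seed,
                train_fraction=config.train_fraction,
                future_stack=future_kept,
            )
            (out / f"eval_{model}.json").write_text(
                json.dumps(result.report.to_dict(), indent=2))
            _emit(out / f"eval_{model}.json")
            scenario_grids = {"current": result.mean_grid}
            if result.mean_future_grid is not None:
                scenario_grids["future"] = result.mean_future_grid
            categories[model] = {}
            for scenario, grid in scenario_grids.items():
                write_ascii_grid(out / f"suitability_{model}_{scenario}.asc",
                                 np.nan_to_num(grid.scores, nan=-9999.0),
                                 grid.georef, mask=grid.mask)
                _emit(out / f"suitability_{model}_{scenario}.asc")
                cat = classify[model](grid)
                write_ascii_grid(out / f"categories_{model}_{scenario}.asc",
                                 cat.codes.astype(float), cat.georef,
                                 mask=cat.mask, fmt="%d")
                _emit(out / f"categories_{model}_{scenario}.asc")
                categories[model][scenario] = cat
            (out / "category_legend.json").write_text(json.dumps(
                {str(i): name for i, name in enumerate(
                    next(iter(categories[model].values())).legend)}, indent=2))
            _done(f"model_{model}", t0)

        # ---- scenario comparison -----------------------------------------
        if future_kept is not None:
            t0 = _stage("compare")
            for model in config.models:
                cur_cat = categories[model]["current"]
                fut_cat = categories[model]["future"]
                report = compare_scenarios(cur_cat, fut_cat, model,
                                           focal_class=config.focal_class)
                (out / f"change_{model}.json").write_text(
                    json.dumps(report.to_dict(), indent=2))
                report.to_table().to_csv(out / f"change_{model}.csv", index=False)
                _emit(out / f"change_{model}.json")
                _emit(out / f"change_{model}.csv")
                tgrid, _counts = transition_map(cur_cat, fut_cat,
                                                config.focal_class)
                write_ascii_grid(out / f"transitions_{model}.asc",
                                 tgrid.astype(float), cur_cat.georef,
                                 mask=cur_cat.mask, fmt="%d")
                _emit(out / f"transitions_{model}.asc")
            _done("compare", t0)
    except Exception as exc:
        manifest["error"] = {"stage": _last_stage(manifest), "cause": repr(exc)}
        manifest["partial"] = True
        (out / "manifest.json").write_text(_manifest_json(manifest))
        raise RuntimeError(
            f"pipeline failed in stage {_last_stage(manifest)!r}: {exc}"
        ) from exc

    (out / "manifest.json").write_text(_manifest_json(manifest))
    return manifest


def _last_stage(manifest: dict) -> str:
    stages = list(manifest["stages"])
    return stages[-1] if stages else "init"


def _manifest_json(manifest: dict) -> str:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, float) and math.isnan(o):
            return None
        raise TypeError(f"not JSON serializable: {type(o)}")
    return json.dumps(manifest, indent=2, default=_default)


def simulate_command(out_dir: str | Path,
                     spec: SyntheticClimateSpec | None = None,
                     envelope: TrueEnvelopeSpec | None = None,
                     deltas: dict[str, float] | None = None,
                     n_points: int = 604,
                     elevation: bool = True,
                     seed: int | None = None) -> dict:
    """Write a complete synthetic study to disk.

    Produces current/ and future/ stack directories, an occurrences CSV and
    a truth.json holding the true envelope so recovery can be verified.
    ``seed`` overrides the spec's seed for all randomness. Synthetic
    elevations (gamma-distributed, mean 700 m) are attached so altitudinal
    summaries have something to chew on.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or default_spec()
    if seed is not None:
        spec.seed = seed
    envelope = envelope or default_envelope()
    deltas = DEFAULT_FUTURE_DELTAS if deltas is None else deltas
    current = make_climate_stack(spec)
    future = make_future_stack(current, deltas)
    write_stack(out / "current", current)
    write_stack(out / "future", future)
    occ = sample_occurrences(current, envelope, n=n_points, seed=spec.seed + 1)
    if elevation:
        rng = np.random.default_rng(spec.seed + 2)
        occ.frame["elevation"] = rng.gamma(shape=2.0, scale=350.0,
                                           size=len(occ)).round(1)
    write_occurrences(occ, out / "occurrences.csv")
    truth = {
        "envelope": {k: list(v) for k, v in envelope.bounds.items()},
        "inside_weight": envelope.inside_weight,
        "outside_weight": envelope.outside_weight,
        "deltas": deltas,
        "seed": spec.seed,
        "n_points": n_points,
        "variables": spec.names,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
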