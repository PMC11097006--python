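"""Fit and validate both suitability models over replicated 70/30 splits:
average the replicate score grids for each scenario, classify them into the
six suitability levels, and report AUC mean +/- sd with its performance band.

Reads results/data/; writes eval_*.json, suitability_*.asc and
categories_*.asc under results/grids/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from ginkgosdm import (classify_bioclim, classify_domain, read_occurrences,
                       read_stack, replicate_evaluation, write_ascii_grid)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=10)
    args = ap.parse_args()

    current = read_stack(args.results / "data" / "current")
    future = read_stack(args.results / "data" / "future")
    occ = read_occurrences(args.results / "data" / "occurrences_thinned.csv")
    grids_dir = args.results / "grids"
    grids_dir.mkdir(parents=True, exist_ok=True)
    classify = {"bioclim": classify_bioclim, "domain": classify_domain}

    for model in ("bioclim", "domain"):
        result = replicate_evaluation(occ, current, model=model,
                                      k=args.replicates, seed=args.seed,
                                      future_stack=future)
        rep = result.report
        print(f"{model}: AUC {rep.mean_auc:.3f} +/- {rep.sd_auc:.4f} "
              f"over {rep.n_replicates} splits -> band '{rep.band}' "
              f"(background n={rep.background_n})")
        (grids_dir / f"eval_{model}.json").write_text(
            json.dumps(rep.to_dict(), indent=2))
        scenarios = {"current": result.mean_grid,
                     "future": result.mean_future_grid}
        for scenario, grid in scenarios.items():
            write_ascii_grid(grids_dir / f"suitability_{model}_{scenario}.asc",
                             np.nan_to_num(grid.scores, nan=-9999.0),
                             grid.georef, mask=grid.mask)
            cat = classify[model](grid)
            write_ascii_grid(grids_dir / f"categories_{model}_{scenario}.asc",
                             cat.codes.astype(float), cat.georef,
                             mask=cat.mask, fmt="%d")
            counts = cat.counts()
            print(f"  {scenario}: "
                  + ", ".join(f"{k}={v}" for k, v in counts.items()))
    print(f"wrote averaged suitability and category grids to {grids_dir}")


if __name__ == "__main__":
    main()
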