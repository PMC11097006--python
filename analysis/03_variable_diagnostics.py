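"""Variable diagnostics at the presence points: descriptive statistics,
stepwise VIF pruning of collinear predictors, and PCA of the correlation
matrix to rank the climatic drivers.

Reads results/data/; writes descriptive_stats.csv, vif_report.{csv,json} and
pca_report.json under results/tables/.
"""

import argparse
import json
from pathlib import Path

from ginkgosdm import (descriptive_stats, extract_at_points, pca,
                       read_occurrences, read_stack, vif_stepwise)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--vif-threshold", type=float, default=5.0)
    args = ap.parse_args()

    stack = read_stack(args.results / "data" / "current")
    occ = read_occurrences(args.results / "data" / "occurrences_thinned.csv")
    env = extract_at_points(stack, occ)
    print(f"extracted {len(env)} x {len(env.variables)} environmental matrix "
          f"({env.n_dropped_nodata} rows on nodata)")

    tables = args.results / "tables"
    tables.mkdir(parents=True, exist_ok=True)

    stats = descriptive_stats(env)
    stats.to_csv(tables / "descriptive_stats.csv")
    print("descriptive statistics (min, max, mean +/- sd, cv, 95% CI):")
    print(stats.to_string())

    vif = vif_stepwise(env, threshold=args.vif_threshold)
    vif.to_frame().to_csv(tables / "vif_report.csv", index=False)
    (tables / "vif_report.json").write_text(json.dumps({
        "threshold": vif.threshold, "kept": vif.kept,
        "dropped": [{"variable": v, "vif": x} for v, x in vif.dropped],
    }, indent=2))
    if vif.dropped:
        print("VIF pruning dropped: "
              + ", ".join(f"{v} (VIF {x:.1f})" for v, x in vif.dropped))
    else:
        print(f"VIF pruning: all {len(vif.kept)} variables below "
              f"{args.vif_threshold} - nothing dropped")

    result = pca(env.subset(vif.kept))
    (tables / "pca_report.json").write_text(json.dumps({
        "eigenvalues": result.eigenvalues.tolist(),
        "proportion_of_variance_pct": result.proportion_of_variance.tolist(),
        "loadings": result.loadings.round(6).to_dict(),
    }, indent=2))
    print("PCA of the correlation matrix:")
    for k in range(min(2, result.n_components)):
        top = result.loadings.iloc[:, k].abs().sort_values(ascending=False)
        print(f"  PC{k + 1}: eigenvalue {result.eigenvalues[k]:.2f}, "
              f"{result.proportion_of_variance[k]:.2f}% of variance; "
              f"top loadings: "
              + ", ".join(f"{v} ({result.loadings.iloc[:, k][v]:+.3f})"
                          for v in top.index[:3]))


if __name__ == "__main__":
    main()
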