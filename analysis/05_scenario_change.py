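"""Compare the current and future classified grids: per-class areas in
10^4 km^2, percent change, retained/lost/new transitions of the excellent
class, and patch fragmentation statistics.

Reads results/grids/; writes change_*.{json,csv} and transitions_*.asc under
results/tables/ and results/grids/.
"""

import argparse
import json
from pathlib import Path

from ginkgosdm import CategoryGrid, compare_scenarios, transition_map
from ginkgosdm.grid import read_ascii_grid, write_ascii_grid


def _read_categories(path: Path) -> CategoryGrid:
    codes, georef, mask = read_ascii_grid(path)
    return CategoryGrid(georef=georef, codes=codes.astype(int), mask=mask)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--focal-class", default="excellent")
    args = ap.parse_args()

    grids_dir = args.results / "grids"
    tables = args.results / "tables"
    tables.mkdir(parents=True, exist_ok=True)

    for model in ("bioclim", "domain"):
        cur = _read_categories(grids_dir / f"categories_{model}_current.asc")
        fut = _read_categories(grids_dir / f"categories_{model}_future.asc")
        report = compare_scenarios(cur, fut, model,
                                   focal_class=args.focal_class)
        print(f"\n{model} per-class areas (10^4 km^2) and change:")
        print(report.to_table().to_string(index=False))
        t = report
        print(f"{args.focal_class} habitat: {t.retained_cells} cells retained "
              f"({t.retained_area} x 10^4 km^2), {t.lost_cells} lost, "
              f"{t.new_cells} new")
        print(f"fragmentation ({args.focal_class}): "
              f"current {t.current_patches.n_patches} patches "
              f"(mean {t.current_patches.mean_patch_cells:.1f} cells), "
              f"future {t.future_patches.n_patches} patches "
              f"(mean {t.future_patches.mean_patch_cells:.1f} cells)")
        (tables / f"change_{model}.json").write_text(
            json.dumps(report.to_dict(), indent=2))
        report.to_table().to_csv(tables / f"change_{model}.csv", index=False)
        tgrid, _ = transition_map(cur, fut, args.focal_class)
        write_ascii_grid(grids_dir / f"transitions_{model}.asc",
                         tgrid.astype(float), cur.georef, mask=cur.mask,
                         fmt="%d")
    print(f"\nwrote change reports to {tables} and transition grids to {grids_dir}")


if __name__ == "__main__":
    main()
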