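"""Clean and thin the presence records: one record per raster cell, then
summarize the spatial extent and the altitudinal class composition.

Reads results/data/; writes results/tables/prepare_summary.json and
results/data/occurrences_thinned.csv.
"""

import argparse
import json
from pathlib import Path

from ginkgosdm import (altitude_class_summary, extent_summary,
                       read_occurrences, read_stack, thin_to_cells,
                       write_occurrences)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    stack = read_stack(args.results / "data" / "current")
    occ = read_occurrences(args.results / "data" / "occurrences.csv")
    print(f"read {len(occ)} records "
          f"({occ.provenance['rejected']} rejected on coordinates)")

    occ = thin_to_cells(occ, stack.georef)
    print(f"thinned to {len(occ)} records, one per grid cell "
          f"({occ.provenance['deduplicated']} removed)")

    lon_min, lon_max, lat_min, lat_max = extent_summary(occ)
    print(f"extent: {lon_min:.1f}-{lon_max:.1f} E, {lat_min:.1f}-{lat_max:.1f} N")

    summary = {
        "n_records": len(occ),
        "provenance": occ.provenance,
        "extent": [lon_min, lon_max, lat_min, lat_max],
    }
    if occ.has_elevation():
        alt = altitude_class_summary(occ)
        summary["altitude_classes_pct"] = alt
        print("altitudinal classes (% of records): "
              + ", ".join(f"{k} {v}" for k, v in alt.items()))

    write_occurrences(occ, args.results / "data" / "occurrences_thinned.csv")
    tables = args.results / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    (tables / "prepare_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {tables / 'prepare_summary.json'}")


if __name__ == "__main__":
    main()
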