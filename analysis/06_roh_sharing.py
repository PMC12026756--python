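#!/usr/bin/env python
"""Cross-sample ROH sharing in 100 kb windows; high-sharing regions.

Tiles the array-panel marker span into 100 kb windows, counts the
fraction of dogs whose ROH touch each window, and merges runs of
windows shared by >90% of the cohort — candidate breed-defining or
positively selected regions.
"""

import argparse
from pathlib import Path

from rohdiv.io_formats import read_hom, read_ped_map
from rohdiv.roh_sharing import (count_sharing, high_sharing_regions,
                                make_windows, regions_to_bed)

parser = argparse.ArgumentParser()
parser.add_argument("--sim", type=Path, default=Path("results/sim"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--threshold", type=float, default=90.0)
args = parser.parse_args()

ds = read_ped_map(args.sim / "array.ped", args.sim / "array.map")
segs = read_hom(args.out / "roh_array.hom")
windows = make_windows(ds.markers, 100_000)
share = count_sharing(windows, segs, {s: "COHORT" for s in ds.samples},
                      {"COHORT": ds.n_samples})
share.to_csv(args.out / "roh_sharing_windows.csv", index=False)
regions = high_sharing_regions(share, "COHORT", args.threshold)
regions.to_csv(args.out / "roh_sharing_regions.csv", index=False)
regions_to_bed(regions, args.out / "roh_sharing_regions.bed")

print(f"{len(windows)} windows of 100 kb over {len(ds.markers.chromosomes())} "
      f"chromosomes; cohort of {ds.n_samples} dogs")
print(f"max sharing {share.pct_COHORT.max():.1f}% "
      f"(window {share.loc[share.pct_COHORT.idxmax(), 'chrom']}:"
      f"{share.loc[share.pct_COHORT.idxmax(), 'start']})")
print(f"{len(regions)} merged regions above {args.threshold}% sharing")
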