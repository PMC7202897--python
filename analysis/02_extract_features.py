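#!/usr/bin/env python
"""Measure the 11 adhesion shape parameters for every non-border cell in the
simulated masks and write results/features.csv (one row per cell).
"""

import argparse
from pathlib import Path

import pandas as pd

from morphoinvasion.morphometry import profile_table, read_mask
from morphoinvasion.synthetic import PIXEL_SIZE_UM

parser = argparse.ArgumentParser()
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--out", type=Path, default=Path("results/features.csv"))
args = parser.parse_args()

by_condition: dict[str, list[Path]] = {}
for f in sorted((args.study / "masks").glob("*.tif")):
    by_condition.setdefault(f.stem.rsplit("_", 1)[0], []).append(f)

tables = []
for condition, paths in by_condition.items():
    masks = [read_mask(p, PIXEL_SIZE_UM) for p in paths]
    tables.append(profile_table(masks, condition, mask_ids=[p.stem for p in paths]))
features = pd.concat(tables, ignore_index=True)
features.to_csv(args.out, index=False, float_format="%.9g")

print(f"measured {len(features)} cells across {len(by_condition)} conditions")
print(features.groupby("condition")[["area", "eccentricity", "compactness"]]
      .mean().round(3).to_string())
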