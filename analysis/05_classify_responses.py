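#!/usr/bin/env python
"""Label each condition low/high (speed > 0.5 um/min; invasion fold > 10)
and run the boosted-stump analyses: single-feature ranking, feature-group
models (all / size / irregularity / elongation) with training and
leave-one-condition-out AUROC, and a hyperparameter grid search.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from morphoinvasion import classification, condition_stats

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("--invasion-threshold", type=float,
                    default=classification.INVASION_THRESHOLD_MESENCHYMAL)
args = parser.parse_args()

features = pd.read_csv(args.results / "features.csv")
metrics = pd.read_csv(args.results / "metrics.csv")
folds = pd.read_csv(args.results / "spheroid_folds.csv")
summaries = condition_stats.summarize(features, metrics, folds)

report = {}
for response, thr in (("speed", classification.SPEED_THRESHOLD),
                      ("invasion", args.invasion_threshold)):
    labeling = classification.label_conditions(summaries, response, thr)
    print(f"\n{response} labels (threshold {thr}): {labeling.labels}")
    if len(set(labeling.labels.values())) < 2:
        print("  single class; classifiers skipped")
        report[response] = {"labels": labeling.labels}
        continue
    ranking = classification.rank_single_features(features, labeling)
    print("  top single features:",
          ", ".join(f"{r.feature} ({r.auroc:.2f})" for r in ranking.head(3).itertuples()))
    groups = classification.evaluate_feature_groups(features, labeling)
    for g in groups:
        print(f"  {g.feature_set:<13} train AUROC {g.auroc_train:.2f}  "
              f"held-out AUROC {g.auroc_cv:.2f}")
    grid = classification.grid_search(features, labeling,
                                      rates=(0.5, 1.0), estimator_counts=(10, 50))
    report[response] = {
        "labels": labeling.labels,
        "ranking": ranking.to_dict("records"),
        "groups": [vars(g) for g in groups],
        "grid": grid.to_dict("records"),
    }

with open(args.results / "classification.json", "w") as fh:
    json.dump(report, fh, indent=1, default=str)
print(f"\nwrote {args.results / 'classification.json'}")
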