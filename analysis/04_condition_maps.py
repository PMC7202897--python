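#!/usr/bin/env python
"""Aggregate per-condition summaries and reproduce the condition-level maps:
rank-correlation/average-linkage clustering of mean-centered profiles, a kNN
graph over standardized single-cell features, and PCA.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from morphoinvasion import condition_stats

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("-k", type=int, default=5)
args = parser.parse_args()

features = pd.read_csv(args.results / "features.csv")
metrics = pd.read_csv(args.results / "metrics.csv")
folds = pd.read_csv(args.results / "spheroid_folds.csv")

summaries = condition_stats.summarize(features, metrics, folds)
frame = condition_stats.summary_frame(summaries)
frame.index.name = "condition"
frame.reset_index().to_csv(args.results / "summaries.csv", index=False, float_format="%.9g")

clust = condition_stats.cluster_heatmap(summaries, "conditions")
fclust = condition_stats.cluster_heatmap(summaries, "features")
emb = condition_stats.knn_graph(features, k=args.k)
scores, loadings, var_frac = condition_stats.pca(features, 2)

with open(args.results / "condition_maps.json", "w") as fh:
    json.dump({
        "condition_leaf_order": clust.leaf_order,
        "feature_leaf_order": fclust.leaf_order,
        "condition_linkage": clust.linkage.tolist(),
        "knn": {"k": emb.k, "n_edges": len(emb.edges)},
        "pca_variance_fractions": var_frac.tolist(),
    }, fh, indent=1)

print("condition dendrogram order:", " -> ".join(clust.leaf_order))
print("feature dendrogram order:  ", " -> ".join(fclust.leaf_order))
print(f"PCA: first two components explain {100 * var_frac.sum():.1f}% of "
      f"single-cell shape variance")
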