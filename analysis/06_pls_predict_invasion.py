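#!/usr/bin/env python
"""Fit the condition-level PLS model from the 11 shape means to speed,
persistence and invasion on the 8-condition recovery study; report R²/Q² per
component, the permutation test, VIP scores, leave-one-condition-out percent
errors, and the new-cell-line augmentation experiment.
"""

import argparse
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from morphoinvasion import condition_stats, motility, pls, synthetic
from morphoinvasion.morphometry import FEATURE_NAMES, profile_table

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--n-cells", type=int, default=50)
parser.add_argument("--out", type=Path, default=Path("results/pls_recovery.json"))
args = parser.parse_args()


def summary_frame(specs):
    study = synthetic.generate_study(specs)
    feats = pd.concat(
        [profile_table(m, c, [f"{c}_{i}" for i in range(len(m))])
         for c, m in study.masks.items()], ignore_index=True)
    return condition_stats.summary_frame(condition_stats.summarize(
        feats, motility.metrics_table(study.trajectories),
        motility.spheroid_table(study.spheroids)))


specs = synthetic.recovery_study_specs(args.seed, n_cells=args.n_cells)
frame = summary_frame(specs)
X = frame[list(FEATURE_NAMES)]
Y = frame[["speed", "persistence", "invasion"]]

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    r2 = pls.r2_per_component(X, Y, 4)
    q2 = pls.q2_loocv(X, Y, 4)
    diag = pls.Diagnostics(R2_per_A=r2[: len(q2)], Q2_per_A=q2)
    A = pls.choose_components(diag)
    model = pls.fit_pls(X, Y, A)
    perm = pls.permutation_test(X, Y, A, n_perm=200, seed=args.seed)
    vip_inv = pls.vip_scores(model, response="invasion").sort_values(ascending=False)

    # leave-one-condition-out invasion percent error
    errs = {}
    for cond in frame.index:
        tr = frame.index != cond
        m = pls.fit_pls(X[tr], Y[tr][["invasion"]], 2)
        rep = pls.predict_new_condition(m, X[~tr], Y[~tr][["invasion"]])[0]
        errs[cond] = rep.percent_error["invasion"]

    # augmentation with a shifted second cell line
    frame_b = summary_frame(synthetic.shifted_line_specs(specs, args.seed))
    XB, YB = frame_b[list(FEATURE_NAMES)], frame_b[["invasion"]]
    held = XB.index[1:]
    base = pls.fit_pls(X, Y[["invasion"]], 2)
    err_before = np.mean([r.percent_error["invasion"] for r in
                          pls.predict_new_condition(base, XB.loc[held], YB.loc[held])])
    aug = pls.augment_and_refit(base, XB.iloc[[0]], YB.iloc[[0]])
    err_after = np.mean([r.percent_error["invasion"] for r in
                         pls.predict_new_condition(aug, XB.loc[held], YB.loc[held])])

print("R2 per component: ", np.round(r2, 3).tolist())
print("Q2 per component: ", np.round(q2, 3).tolist())
print(f"chosen A = {A}; permutation p = {perm.p_value:.3f} "
      f"(observed Q2 {perm.observed_q2:.2f})")
print("invasion VIPs >1:",
      ", ".join(f"{k} ({v:.2f})" for k, v in vip_inv.items() if v > 1))
print(f"leave-one-condition-out invasion %error: mean {np.mean(list(errs.values())):.1f}, "
      f"max {max(errs.values()):.1f}")
print(f"new-line error before augmentation {err_before:.1f}%, after {err_after:.1f}%")

args.out.parent.mkdir(parents=True, exist_ok=True)
with open(args.out, "w") as fh:
    json.dump({
        "seed": args.seed, "A": A,
        "R2_per_A": r2.tolist(), "Q2_per_A": q2.tolist(),
        "permutation_p": perm.p_value,
        "vip_invasion": vip_inv.to_dict(),
        "loo_percent_error": errs,
        "augmentation": {"before": err_before, "after": err_after},
    }, fh, indent=1)
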