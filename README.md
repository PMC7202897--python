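# morphoinvasion

Predicting ECM-driven 3D invasion of breast cancer cells from
cell-adhesion morphometry.

## The problem

Tumor stroma is rich in extracellular-matrix (ECM) proteins — Collagen I,
Collagen IV, Fibronectin, Tenascin C — and each of them can push cancer
cells toward invasion and metastasis. Testing every candidate ECM cue in a
3D spheroid invasion assay is slow; a 2D adhesion assay (plate cells on a
coated surface, fix after 2 h, segment, measure) is fast. This package
implements the analysis pipeline that connects the two: it quantifies cell
shape on each ECM cue, quantifies 2D migration and 3D invasion, and asks —
with classifiers and latent-variable regression — whether the cheap
measurement predicts the expensive one.

The core quantities:

* **11 shape parameters** per segmented cell: area, perimeter, mean radius,
  min/max Feret diameter, aspect ratio, eccentricity, compactness, extent,
  form factor, solidity. They fall into three empirical families — size,
  elongation (eccentricity, aspect ratio, compactness) and irregularity
  (solidity, extent, form factor).
* **2D migration**: speed = path length / time; persistence = net
  displacement / path length ∈ [0, 1].
* **3D invasion**: spheroid area fold change, day 5 / day 1.
* **Classification**: conditions are labeled low/high (speed > 0.5 µm/min;
  fold change > 10 or > 8), and discrete AdaBoost over decision stumps
  (α_t = ½ ln((1−ε_t)/ε_t)) is trained on per-cell features, scored by
  AUROC with leave-one-condition-out folds.
* **Regression**: NIPALS PLS from autoscaled condition-level shape means to
  speed, persistence and invasion, with R², leave-one-out Q² = 1 − PRESS/TSS,
  a permutation null for Q², VIP scores (Σ VIP² = #predictors, VIP > 1 =
  important), and percent-error prediction of new conditions and new cell
  lines.

Because the original single-cell measurements live only in published
figures, the package ships a first-class synthetic-data generator whose
shape→invasion coupling is known exactly, so every stage is testable and
the whole pipeline can be exercised end to end. See `docs/methods.md` for
the model details and what the synthetic data does and does not emulate.

## Worked example

The numbered scripts under `analysis/` run the full study; each writes its
tables under `results/` and prints what it found.

```bash
python analysis/01_simulate_study.py --seed 0     # 5-condition demo study
python analysis/02_extract_features.py            # 11 features per cell
python analysis/03_motility_metrics.py            # speed/persistence/folds
python analysis/04_condition_maps.py              # clustering, kNN, PCA
python analysis/05_classify_responses.py          # low/high AdaBoost models
python analysis/06_pls_predict_invasion.py        # PLS recovery experiment
```

With seed 0 the feature stage prints per-condition means

```
                 area  eccentricity  compactness
CollagenI    1897.382         0.788        1.347
CollagenIV   1475.167         0.769        1.361
Fibronectin  1581.928         0.647        1.172
TenascinC     626.823         0.420        1.019
noECM        1014.163         0.519        1.038
```

— collagens elongate and enlarge cells, Tenascin C shrinks and rounds them —
and the condition-map stage reports

```
PCA: first two components explain 83.9% of single-cell shape variance
```

The invasion stage labels the collagens "high" (mean folds 12.4 and 13.6,
above the 10× threshold) and the rest "low", and the PLS recovery run on
the 8-condition coupled study prints

```
chosen A = 2; permutation p = 0.090 (observed Q2 0.23)
invasion VIPs >1: aspect_ratio (1.86), eccentricity (1.81), compactness (1.52)
leave-one-condition-out invasion %error: mean 10.4, max 25.3
new-line error before augmentation 60.3%, after 50.8%
```

i.e. the variables the model flags as important for predicting invasion are
exactly the elongation features the generator coupled to invasion; a
held-out condition's fold change is predicted to ~10% on average; and a new
"cell line" with a shifted invasion baseline is predicted substantially
better once its single baseline condition is added to the training set.

There is also a console entry point mirroring the stages
(`morphoinvasion simulate|features|motility|embed|pipeline run`), e.g.

```bash
morphoinvasion pipeline run --config configs/demo.yaml
```

where the YAML config names the output directory, seed, thresholds and PLS
settings; the run writes a `manifest.json` with stage timings and SHA-256
hashes of every output, and reruns with the same seed are byte-identical.

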