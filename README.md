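# thermobreast

Statistical and texture description of breast thermograms for
control-vs-anomaly classification, with a synthetic thermal-cohort
simulator so the whole pipeline is testable without clinical data.

## The problem

During tumour development, angiogenesis increases blood flow and raises
the skin temperature over the affected area. An infrared camera records
this as a *thermogram* — a grid of surface temperatures in °C. The
analysis question is whether a short, interpretable set of per-breast
descriptors can separate breasts with thermal anomalies (label `A`) from
controls (`NA`). This package implements that analysis end to end for
researchers working with radiometric temperature exports and binary
breast masks:

1. **ROI extraction** (`thermobreast.io`) — read plain-text temperature
   grids and bilevel masks, split the masked breast region at the
   vertical midline of its bounding box into individual left/right
   breast samples.
2. **Feature extraction** (`thermobreast.features`) — 13 descriptors per
   breast. Nine pixel statistics on the in-mask temperatures `T(x,y)`:
   mean μ, population standard deviation σ and variance σ², Pearson-type
   skewness γ = (μ − median)/σ, non-excess kurtosis k = E(x−μ)⁴/σ⁴,
   Shannon entropy H = −Σ pᵢ log₂ pᵢ (bits), min, max, coefficient of
   variation CV = σ/μ·100, and energy E = Σ T(x,y) (the temperature
   sum). Plus three texture features from a masked, symmetric,
   direction-integrated gray-level co-occurrence matrix P(i,j) over the
   four distance-1 directions {0°, 45°, 90°, 135°}:
   homogeneity Σ P(i,j)/(1+(i−j)²), contrast Σ (i−j)² P(i,j), and
   correlation Σ (i−μₓ)(j−μᵧ) P(i,j)/(σₓσᵧ), computed on G = 256
   quantized gray levels.
3. **Feature selection** (`thermobreast.selection`) — per-feature Welch
   two-sample t-test, tᵢ = (X̄ᵢ,₁ − X̄ᵢ,₂)/√(s₁ᵢ²/n₁ + s₂ᵢ²/n₂), retaining
   features with p < 0.05.
4. **Classification** (`thermobreast.classify`) — linear SVM, quadratic
   SVM, logistic regression and a coarse decision tree (≤ 4 splits),
   under stratified k-fold cross-validation with accuracy, precision,
   recall, specificity and F1.
5. **Statistical validation** (`thermobreast.evaluation`) — percentile
   bootstrap confidence intervals (B = 2000) for every metric, and exact
   pairwise McNemar tests on the discordant prediction counts.
6. **Simulation** (`thermobreast.synthetic`) — synthetic cohorts of
   bilateral temperature fields with hotspots and vessel-like warm
   structures on anomalous breasts, emulating a clinical cohort of 265
   per-breast samples (71 `A` / 194 `NA`).

## Worked example

```python
import thermobreast as tb
from thermobreast.features import features_table
from thermobreast.selection import select_features
from thermobreast.classify import stratified_kfold, cross_validate

cfg = tb.study_config()            # 97 control + 42 cancer subjects, 29 bilateral
samples = tb.study_samples(cfg)    # 265 breast samples: 71 A / 194 NA
table = features_table(samples)
sel = select_features(table, alpha=0.05)
print(sel.selected)
plan = stratified_kfold(table["label"], k=5, seed=cfg.seed)
run = cross_validate("ct", table[sel.selected], table["label"], plan)
print(f"CT accuracy {run.mean_metrics['accuracy']:.4f} +/- {run.sd_metrics['accuracy']:.4f}")
```

prints

```
['mean', 'std', 'variance', 'skewness', 'kurtosis', 'entropy', 'max', 'cv', 'energy', 'homogeneity', 'contrast', 'correlation']
CT accuracy 1.0000 +/- 0.0000
```

Twelve of the 13 descriptors pass the Welch test here and the coarse
tree classifies every held-out breast correctly: the simulator's default
2 °C hotspots over 0.2 °C pixel noise are a *strong* thermal signal, so
near-perfect cross-validated accuracy is the expected outcome, not a
bug. Shrink `hotspot_delta` (or raise `noise_sd`) to explore harder
regimes; with `hotspot_delta=0` the selection retains each feature at
the nominal 5% false-positive rate and accuracy falls to the 194/265 ≈
0.73 majority rate.

The same chain is available from the shell:

```
thermobreast simulate --config cohort.yaml --out DIR --seed 7
thermobreast extract  --manifest DIR/manifest.csv --out features.csv
thermobreast select   --features features.csv --out sel/
thermobreast evaluate --features features.csv --selection sel/selected.json --out report/ --seed 7
thermobreast run      --config run.yaml --out report/ --seed 7   # all of the above
```

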