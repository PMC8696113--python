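# tred — cell-phenotype classification from transmembrane-receptor trajectories

Single-particle tracking (SPT) of membrane receptors such as EGFR yields
thousands of short 2D trajectories per experiment. The lateral motion of
those receptors reflects membrane composition, cytoskeletal organisation
and receptor–receptor interactions, so the trajectories carry a
biophysical fingerprint of the cell that produced them. Classical
analysis compresses each trajectory into a mean-squared-displacement
(MSD) curve and reads off a diffusivity *D* and a confinement size *L*,
discarding most of the information in the raw time series.

`tred` implements the alternative: feed the trajectories themselves to a
deep classifier and let it learn the discriminative features. It is
aimed at biophysicists and image-analysis researchers who have tracked
receptor trajectories (any per-localization CSV/TSV export) and want to
ask: *can the cell of origin — or a coarser phenotype group — be read
off the receptor dynamics?*

## What it does

1. **Preprocessing.** Raw tracks of variable duration (up to ~1,200
   steps at dt = 50 ms) are cut into non-overlapping 300-step segments;
   segments of stalled receptors (spatial extent indistinguishable from
   localization noise) are removed; survivors are recentred to the
   origin, randomly shuffled *within their class*, and stitched in runs
   of ten into 3,000-step **reassembled trajectories**. Every model
   input therefore carries the same amount of dynamic information.
2. **Classification.** A 14-layer 1D residual network (one stem
   convolution, six residual blocks of two convolutions, one fully
   connected softmax head) maps each reassembled trajectory — encoded as
   its per-step displacement channels (Δx, Δy) — to class
   probabilities. Training uses SGD with momentum and categorical
   cross-entropy; the tuned defaults are learning rate 5·10⁻⁴, weight
   decay 5·10⁻⁴, dropout 0.4, batch size 32.
3. **Evaluation.** Stratified 5-fold cross-validation (64% train / 16%
   validation / 20% test per trial), row-normalized confusion matrices,
   per-class one-vs-rest ROC/AUC, and 2D UMAP projections of the
   penultimate-layer features. A fine→coarse label scheme (e.g. breast
   cancer cell lines → HR+/HER2+/TN receptor status) supports grouped
   classification and testing pretrained models on perturbed datasets.
4. **Synthetic data.** A seeded simulator produces labeled multi-class
   datasets (Brownian, confined, fractional-Brownian, directed and
   stalled motion with localization noise) plus MSD utilities
   (`compute_msd`, `fit_msd`) that double as physical oracles, so the
   entire pipeline is testable without any experimental download.

The classifier follows the scikit-learn estimator API
(`fit` / `predict` / `predict_proba` / `get_params`), so it composes
with sklearn model selection.

## Worked example

```python
import numpy as np
from tred import (benchmark_spec, generate_dataset, preprocess_dataset,
                  PreprocessConfig, cross_validate, average_msd, fit_msd)

# 1. simulate a six-class benchmark (32 tracks per class, 10% stalled)
dataset = generate_dataset(benchmark_spec(n_tracks=32, seed=42))
print(f"simulated {len(dataset)} tracks, classes: {dataset.label_set}")

# 2. classical MSD analysis of one class
fast = [t for t in dataset if t.label == "bro-fast"][:50]
fit = fit_msd(average_msd(fast, 50), "brownian")
print(f"MSD estimate for 'bro-fast': D = {fit.D:.4f} um^2/s (true 0.12)")

# 3. preprocess: 30-step segments -> 300-step reassembled trajectories
config = PreprocessConfig(segment_length=30, target_length=300)
reassembled, report = preprocess_dataset(dataset, config, seed=7)

# 4. stratified 5-fold cross-validated classification
result = cross_validate(reassembled.to_array(), reassembled.labels,
                        k=5, seed=0, max_epochs=25, early_stop_patience=8,
                        compute_features=False)
print(f"5-fold CV accuracy: {result.accuracy:.3f}")
print(result.confusion_normalized.round(2))
```

Output (3 minutes on one CPU core):

```
simulated 192 tracks, classes: ['bro-fast', 'bro-mid', 'bro-slow', 'conf-large', 'conf-small', 'fbm-sub']
MSD estimate for 'bro-fast': D = 0.1085 um^2/s (true 0.12)
5-fold CV accuracy: 0.844
            bro-fast  bro-mid  bro-slow  conf-large  conf-small  fbm-sub
bro-fast        0.90     0.00       0.0        0.06        0.00     0.03
bro-mid         0.00     0.85       0.0        0.00        0.15     0.00
bro-slow        0.00     0.00       1.0        0.00        0.00     0.00
conf-large      0.06     0.00       0.0        0.62        0.31     0.00
conf-small      0.00     0.14       0.0        0.18        0.68     0.00
fbm-sub         0.00     0.00       0.0        0.00        0.00     1.00
```

The MSD fit recovers the input diffusivity up to Monte-Carlo and
localization-noise error. The confusion matrix is read row-wise: 90% of
fast-Brownian inputs are classified correctly, and the residual
confusion concentrates — as it should — between the two confinement
sizes, which differ only in plateau, not in microscopic diffusivity.

The same pipeline is available from the shell:

```bash
tred simulate --n-tracks 32 --seed 42 --out run/sim
tred preprocess --in run/sim/trajectories.csv --segment-length 30 \
     --target-length 300 --seed 7 --out run/prep
tred evaluate --in run/prep/reassembled.csv --seed 0 --out run/eval
```

Each stage writes a JSON manifest (inputs, seeds, version, counts) so a
run is reproducible from its manifests alone. For experimental data,
point `tred preprocess` at your per-localization table (columns
`track_id,frame,x_um,y_um,label`, configurable via `tred.io.Dialect`)
and keep the full-scale defaults `--segment-length 300 --target-length
3000`; the stall-filter thresholds are configurable to match your
localization precision.

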