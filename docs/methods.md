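# Methods

## Problem setting

Input data are two-dimensional single-particle-tracking (SPT)
trajectories of membrane receptors: per-localization tables
(track id, frame index, x, y in µm) acquired at a fixed frame interval
dt (default 0.05 s). Track durations vary from a few steps up to about
1,200 steps (one minute). The task is supervised: each track carries a
class label (its cell of origin, or a coarser phenotype group), and the
pipeline learns to predict that label from motion alone.

## Preprocessing: equal-information inputs

Variable-length tracks are not directly comparable: a long track simply
contains more evidence than a short one, and a length-aware classifier
would exploit acquisition artifacts rather than dynamics. The pipeline
therefore converts raw tracks into fixed-length inputs:

1. **Segmentation.** Each track is cut into non-overlapping windows of
   `segment_length` steps (default 300). Windows never span a gap in
   the frame index (`gap_policy="split"`); maximal contiguous runs are
   windowed separately, because bridging a gap would fabricate a
   displacement that was never observed. A `bridge` policy exists for
   data whose gaps are known to be negligible. Trailing remainders are
   discarded, not padded.
2. **Stall filter.** A segment is discarded as *stalled* when its
   maximum pairwise displacement is below `max_span_um` (default
   0.2 µm) **or** its radius of gyration is below `min_rg_um` (default
   0.05 µm). An immobilised or nonspecifically stuck emitter produces a
   localization-noise cloud of extent ≈ σ_loc (typically 0.02–0.05 µm);
   the defaults sit a few multiples above that, so genuine diffusion at
   D ≥ 0.05 µm²/s over 300 steps is retained at ≥ 95% while pure noise
   clouds are removed at ≥ 95% (both verified in the test suite).
   Either criterion can be disabled; both are config keys so they can
   be matched to a particular instrument's precision.
3. **Recentring.** Surviving segments are translated to start at the
   origin. Only relative motion is informative; absolute field-of-view
   coordinates are an acquisition artifact.
4. **Shuffle and stitch.** Within each class, segments are permuted by
   a seeded RNG and stitched in runs of `target_length/segment_length`
   (default 3,000/300 = 10) into one *reassembled trajectory*. Segments
   may mix source tracks within a class; cross-class mixing is
   forbidden. Leftover runs shorter than ten segments are discarded.

**Stitching geometry.** Each subsequent segment is translated so that it
continues from the previous segment's end point *offset by its own first
displacement*. Ten identical straight-line segments therefore stitch
into one continuous straight line, and the join step has the correct
marginal step distribution for memoryless motion (it replicates the
incoming segment's first step, rather than inserting an artificial jump
or a zero-length stall). The count identity R = 10·S positions is
preserved. An alternative `stitch="origin"` mode concatenates
origin-anchored segments without translation, for sensitivity analysis
of the stitching choice. Under the default displacement encoding (see
below) the two modes differ only in the ten join steps per input.

Per label, the counts satisfy the conservation identity
`segments_produced = segments_removed + 10·n_reassembled + leftover`
with `0 ≤ leftover < 10`; the preprocessing report records every stage
count and the seed, and the identity is checked against an independent
recount in the tests.

## The classifier

A 14-layer 1D residual network:

* stem: 1D convolution, kernel 7, stride 2, `base_channels` filters
  (default 64), batch norm, ReLU, max pool (kernel 3, stride 2);
* three stages of two residual blocks each, channel widths 1×/2×/4×
  `base_channels`, stride-2 downsampling with a projected (1×1
  convolution) shortcut at the entry of stages two and three; each
  block is conv(3)–BN–ReLU–conv(3)–BN plus shortcut, then ReLU;
* global average pooling over time, dropout (default 0.4), linear
  softmax head.

Weight-bearing layers on the main path: 1 stem + 6×2 block convolutions
+ 1 head = 14. Following the usual ResNet depth-counting convention,
the two projection shortcuts are not counted; both counts are exposed
(`weight_layer_count`, `projection_layer_count`) and asserted in the
tests so the architecture cannot drift silently.

**Input encoding.** Each reassembled trajectory is encoded as its
per-step displacement sequence (Δx, Δy): 2 channels × (R−1) steps,
standardized per channel with mean/scale computed **from the training
split only**. Displacements make predictions exactly invariant to a
constant translation of the input (asserted as an exact equality test)
and equalize scale across classes. A `positions` encoding
(start-anchored coordinates) is retained for ablation.

**Training.** SGD with momentum 0.9, constant learning rate, L2 weight
decay on convolution/linear weights (not on batch-norm parameters or
biases), categorical cross-entropy. Tuned defaults: learning rate
5·10⁻⁴, weight decay 5·10⁻⁴, dropout 0.4, batch size 32. Epoch budget:
`max_epochs` 100 with early stopping on validation loss (patience 10);
the weights of the best validation epoch are restored. Arg-max ties at
prediction resolve to the lowest class index. The engine is float32
NumPy with explicit `numpy.random.Generator` seeding of weight
initialisation, batch order and dropout masks, so a run is
bit-reproducible for a given seed on a given BLAS build; across BLAS
builds reproducibility is best-effort (summation order may differ).

The engine's backward passes are hand-derived and are checked against
central-difference oracles layer by layer in the test suite.

## Evaluation protocol

Samples are split into k = 5 stratified folds (20% of the data each).
For each trial the remaining four folds are split again, stratified,
into 80% training and 20% validation — i.e. 64% / 16% / 20% of the
whole dataset. With class counts divisible by 25 these fractions are
exact; otherwise they hold to ±1 sample per class (largest-remainder
allocation inside scikit-learn's stratified splitters, which stand
behind `make_fold_plan`). One network is trained per fold; its test
fold never influences training, early stopping or normalization
statistics.

Confusion matrices are **pooled over raw per-fold counts** and then
row-normalized; per-fold matrices are retained in the report
(averaging normalized per-fold matrices is the alternative; pooling
weights every sample equally and keeps the matrix consistent with the
pooled accuracy recount). ROC analysis is one-vs-rest per class with
trapezoidal AUC; a class without positives or negatives is flagged as
undefined rather than given a number. UMAP projections of the
penultimate-layer features use n_neighbors = 15, min_dist = 0.1 and a
fixed random_state (the embedding is qualitative; no metric depends on
it).

For pretrained-model evaluation on new datasets, true labels may be
regrouped through a fine→coarse `LabelScheme` (the built-in
`RECEPTOR_STATUS_SCHEME` maps six breast-cancer cell lines to
HR+/HER2+/TN); labels unseen at training time contribute confusion rows
but no prediction column. Dataset-shift comparisons report per-class
predicted-fraction deltas as relative percent change
((after−before)/before·100, so 0.19 → 0.46 is +142%).

## Synthetic data generator

The simulator emulates the statistical structure the pipeline assumes,
one regime per class:

| regime    | model                                                        |
|-----------|--------------------------------------------------------------|
| brownian  | i.i.d. Gaussian steps, per-axis variance 2·D·dt              |
| confined  | Brownian microsteps with specular reflection in a square box of side L centred on the start |
| fbm       | fractional Gaussian increments (Davies–Harte circulant embedding, Cholesky fallback) |
| directed  | Brownian plus constant drift of speed v, random direction    |
| stalled   | fixed emitter, motion is pure localization noise             |

All positions are then perturbed by i.i.d. Gaussian localization noise
(σ_loc, default 0.02 µm per axis). Track durations are drawn uniformly
from a configurable range (default 300–1,200 steps); a deterministic
`floor(stalled_fraction·n)` of each class's tracks are replaced by
stalled emitters so the filter always has work to do.

**fBm convention.** Anomalous diffusion makes the unit of D ambiguous.
Here per-axis MSD(τ) = 2·D·τ^{2H}·t₀^{1−2H} with reference time
t₀ = 1 s, so D keeps the unit µm²/s for every Hurst exponent and
H = 0.5 reduces exactly to Brownian motion (verified distributionally
in the tests).

**Default six-class benchmark** (`benchmark_spec`): Brownian D = 0.02 /
0.05 / 0.12 µm²/s; confined D = 0.1 with L = 0.3 / 0.6 µm; fBm D = 0.08,
H = 0.35. The classes group 1/2/3 into three coarse groups, mirroring a
cell-line → receptor-status regrouping. The values are illustrative
diffusion regimes spanning the range typical of membrane-receptor SPT;
they are not calibrated to any particular cell line.

**What passing tests do and do not show.** The simulator produces
stationary, homogeneous motion with uncorrelated Gaussian localization
noise. Real receptor trajectories switch diffusive states within one
track, show cell-to-cell heterogeneity within a class, and carry
blinking/mislinking artifacts — none of which are modelled. Green tests
therefore certify that the pipeline is *correct* (counts conserved,
statistics unbiased, classifier able to recover known class structure
well above chance), not that any particular biological classification
accuracy will be achieved on experimental data.

## MSD utilities

`compute_msd` is the time-averaged MSD over all ordered pairs,
MSD(n·dt) = ⟨|r(t+n·dt) − r(t)|²⟩_t. `fit_msd` extracts D from the
weighted least-squares slope over the first 10 lags (slope/4; the
intercept absorbs the localization-noise floor 4σ_loc²), or fits the
saturating form P·(1−e^{−τ/τc})+c for confined motion. For a square box
the stationary uniform distribution gives plateau P = L²/3 (per-axis
variance L²/12, doubled for the difference of two independent
positions, doubled again for two axes), hence L = √(3P) and
D = P/(4τc).

## Problem sizes used by tests and the acceptance script

Tests and `scripts/acceptance.py` run the full pipeline at desk scale,
chosen so the whole suite completes in minutes on one CPU core:
reassembled trajectories of 300 steps built from 30-step segments
(the 10-segment structure is preserved), 32 simulated tracks per class
(≥ 60 reassembled trajectories per class), 5-fold cross-validation with
`max_epochs` 25 and patience 8. The engine-behaviour unit tests use a
narrow network (`base_channels=8`) on short inputs; architecture,
optimizer and data flow are identical to the full-scale configuration.
Full-scale runs (300/3,000 steps, 64 channels, 100 epochs) use the same
code paths and are exercised through the CLI defaults.

## Known limitations

* Training on 3,000-step inputs at the default width is CPU-intensive
  (minutes per epoch for ~2,000 samples); the engine is single-threaded
  NumPy + BLAS and does not use a GPU.
* Batch normalization uses batch statistics during training; very small
  batch sizes (< 8) degrade its estimates.
* The confined-motion fit assumes a square box; other geometries bias
  the recovered L by their shape factor.
* `is_stalled` computes the exact pairwise diameter (O(S²) per
  segment); for segment lengths far beyond 300 a convex-hull diameter
  would be preferable.
* UMAP determinism holds for a fixed seed and package version; the
  embedding is for visualisation only.
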