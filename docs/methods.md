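# Methods

## Signal model and ground truth

The phantom renders magnitude inversion-recovery signal
`S(TI) = PD · |1 − 2 e^(−TI/T1)|`, which assumes a perfect 180° inversion
and full recovery between acquisitions. The myocardial null is then exactly
`TI = T1 · ln 2`, giving every simulated series an analytic ground truth:
the *true null frame* is the sampled TI closest to `T1 ln 2`, ties broken
to the earlier frame (the discrete choice a human reader makes). Series
whose TI grid does not bracket the null are rejected as misconfigured.

Scene geometry is deliberately minimal: a blood-pool disc inside a
myocardial annulus on a uniform low-proton-density background, with
per-series jitter of centre and radii. Post-contrast T1 defaults
(myocardium 350–500 ms, blood 250–320 ms) put the blood null before the
myocardial null, reproducing the dark-blood → bright-blood evolution the
selector relies on. Noise is Rician (the magnitude-image noise family),
`sqrt((S+n₁)² + n₂²)` with `n₁, n₂ ~ N(0, σ)` and σ = 0.03 relative to unit
proton density by default; a Gaussian option exists for tests.

Default cohort conditions (`simulate_dataset`): 64 px frames, 14–26 frames
per series, TI start 120–180 ms, TI step 25 ms (within the 8–46 ms range
enforced by `PhantomConfig`), one noise realisation per series. These were
fixed once as a desk-scale analogue of clinical scouts (which run 9–100
frames at 9–45 ms resolution and larger matrices) and are not tuned.

What the phantom does **not** emulate: cardiac/respiratory motion,
arrhythmia-induced frame corruption, partial-volume myocardium, abnormal
contrast kinetics (e.g. amyloid), coil-shading, multi-vendor pulse-sequence
contrast differences, or PSIR reconstruction. Passing the phantom study
therefore demonstrates that the implementation learns and decodes the
intended transition signal; it does not certify clinical performance.

## Labelling and training-time sampling

Frames before the annotated null get label 0, frames after it 1, and the
null frame itself the soft label 0.5; the label vector is monotone with
exactly one 0.5. Per epoch and series the sampler draws a splice of nine
consecutive frames containing the null, drops two random frames (never the
null) to emulate coarser temporal resolution, and slides a width-3 stride-1
window over the remaining seven frames, yielding five windows whose
training targets are their centre-frame labels.

Two details are under-determined by the general scheme and were fixed as
follows:

* **Splice-start distribution.** Starts are drawn from a triangular
  weighting over admissible starts, peaked where the null lands at the
  splice centre (a one-parameter realisation of oversampling near the
  null); a uniform option exists. Starts that would pin the null to a
  splice edge are avoided when alternatives exist, so that the 0.5 target
  survives windowing.
* **Frame dropping.** The two removed frames are drawn uniformly from the
  removal pairs that keep the null frame at an interior position of the
  seven kept frames (so it remains a window centre). Without this
  constraint a boundary null can lose its 0.5 window entirely.

Validation and inference use no splicing, dropping or oversampling: a
series of n frames is passed as is, as its n − 2 windows of three
consecutive frames.

Images are standardised with corpus-level mean and variance (computed once
over the whole training corpus, stored in the model bundle, reused at
inference) and resized bilinearly to the model resolution. Augmentation —
horizontal flips (p = 0.5), rotations within ±10°, intensity scaling ±10%,
applied identically to a window's three channels — is on during training
and off at inference.

## Architecture

Each window (3 channels = earliest/middle/latest frame) passes through a
CNN backbone: VGG16, ResNet18 or SE-ResNet18 (ResNet18 with
squeeze-and-excitation channel recalibration in every basic block,
reduction ratio 16). The pooled backbone output is projected by a learned
linear layer to a 1024-dimensional window embedding (for VGG16, through a
4096-unit hidden layer first). A single-layer bidirectional LSTM (hidden
512 per direction) reads the embedding sequence and a one-unit dense layer
per timestep performs logistic regression, emitting one probability per
window. The full-scale SE-ResNet18 variant has ≈18 M trainable parameters
— the same order as the tens of millions a production-scale CNN-LSTM of
this design carries.

The networks are built on `tiscout.nn`, a compact NumPy engine (im2col
convolutions, batch normalisation, max pooling, SE blocks, explicit
backward-through-time LSTM, Adam with parameter groups). Every layer's
analytic gradient is checked against central finite differences in float64
in the test suite. The LSTM initialises its forget-gate bias to 1
("remember by default"), the standard stabilisation; it is what lets a
recurrent net trained on five-window sequences decode much longer series
without mid-sequence probability drift.

A `tiny` preset (64 × 64 input, base width 8, 128-d embedding, hidden 64)
makes the entire pipeline trainable in minutes on one CPU; the full-scale
spec is the default.

## Training

Weighted binary cross-entropy over windows, with per-window weight
`min(|ln(Tᵢ/T_opt)|⁻¹, 3)` where `Tᵢ` is the window's centre TI and
`T_opt` the annotated null frame's TI (the decoded quantity is the centre
TI, so the weight axis matches). The weight diverges at the null — the cap
of 3 is returned exactly there — and decays symmetrically in the TI ratio,
focusing the loss near the transition. Weights are absolute, not
renormalised per batch.

Optimisation is Adam (β = 0.9/0.999, classic L2 weight decay 1e-4) with a
*differential learning rate*: one parameter group for the feature extractor
(backbone + 1024 projection) and one for the recurrent stage + head. The
default `TrainConfig` is the production recipe — 30 epochs, batch 32 (of
series; 5 windows each), 1.5e-2 / 3e-3, constant rates (an exponential
decay option exists but is off). `TrainConfig.desk_scale` is the matched
recipe for the tiny preset — 15 epochs and 3e-3 / 1e-3, since
width-reduced networks need proportionally smaller steps; at the
production rates the tiny model's loss oscillates around its floor instead
of settling.

Cross-validation is five-fold at the series level (a series never spans
folds), 80/20 by construction, with the best fold selected by lowest
validation MAE (ties: higher within-50-ms accuracy, then lower fold id).
All randomness — initialisation, shuffling, splice/drop/augmentation —
flows from one seed; identical seeds reproduce identical parameters
bit-for-bit.

## Decoding

The operative rule: the window whose probability is closest to 0.5, ties
to the earliest window; the prediction is that window's centre-frame TI,
so predictions are always sampled TIs and never the first or last frame. A
`latest` tie-break and an alternative transition-point decoder (first 0.5
crossing of the monotone-smoothed trace) are available but off by default.
Exact probability ties are vanishingly rare in float arithmetic; the
deterministic rule simply makes behaviour reproducible.

## Agreement statistics

`evaluate` assembles: accuracy within a threshold (default 50 ms,
boundary inclusive), MAE/MSE, Lin's concordance correlation coefficient
(population moments, per Lin's definition), Bland–Altman bias and 95%
limits (sample SD, 1.96 multiplier), and reduced major axis regression
(slope = sign(r)·sd(pred)/sd(truth), for which the moment convention
cancels). Differences are **prediction − truth** throughout, so positive
bias = TI overestimation; the convention is stated in the module docstring
because the opposite choice flips the Bland–Altman sign. The concordance
histogram uses half-open 25-ms bins, edge values to the upper bin.

## Saliency

Spatial saliency backpropagates the selected window's pre-logistic score
to the input pixels (the decision-relevant scalar), sums absolute
gradients over the up-to-three windows each frame belongs to, and
optionally smooths with a Gaussian (default σ = 2 px; σ = 0 is the
identity). Temporal saliency is each frame's map mean. On converged
phantom models the attention concentrates on the myocardial annulus and
the temporal profile peaks near the predicted null; both are asserted in
the tests.

## Problem sizes and numerical choices

The test suite and the acceptance script run the recovery study at 200
training / 50 held-out series, tiny preset, 15 epochs — sizes chosen so a
full from-scratch run completes in minutes on a single CPU while leaving
the learning problem non-trivial (varying T1, grid origin, length,
geometry and noise per series). Probabilities are clipped at 1e-12 inside
the loss; network arithmetic is float32 (float64 only in gradient-check
tests); BatchNorm uses ε = 1e-5, momentum 0.1. Degenerate inputs (empty
series, series shorter than 9 frames for training or 3 for inference,
zero-variance normalisation, non-bracketing TI grids) raise errors naming
the offending series.

## Known limitations

* The phantom's simplicity means recovery results bound implementation
  correctness, not clinical accuracy; vendor-specific contrast behaviour
  is represented only by the TI-tag dialects.
* The exact oversampling distribution around the null and the
  augmentation inventory of the original training protocol are not public;
  the triangular scheme and the conservative flip/rotate/scale policy are
  this package's stand-ins.
* The mapping from backbone width to the 1024-d embedding is realised as a
  learned linear projection of the pooled features; other realisations
  (e.g. flattened-feature projection) would change parameter counts.
* Only single-layer bidirectional recurrence is implemented.
* DICOM support covers single-frame-per-file series with the standard
  rescale/photometric tags; multi-frame objects and DICOM networking are
  out of scope.
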