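# Methods

## Problem and model

The package addresses supervised binary classification of per-pixel skin
reflectance spectra (basal cell carcinoma vs healthy) in the
visible/near-infrared range, and the pixel-wise segmentation of whole
hyperspectral cubes that follows from it.  The classifier is a hybrid: a 1D
convolutional network learns a feature map, and a kernel SVM replaces the
network's sigmoid output as the final activation layer.  The network never
sees the full 398–995 nm sensor range; spectra are first cropped to the
closed window [573.45, 779.88] nm, where the two tissue classes differ,
which on the 398.08 + k·2.2 nm grid keeps exactly 94 channels.

### Backbone

Inception modules for 1D signals: four parallel branches — convolutions
with receptive fields 1, 3 and 5, and a width-3 max pool followed by a 1×1
projection convolution — each same-padded with stride 1 so the spectral
length is preserved, batch-normalised *before* activation, and concatenated
channel-wise.  Branch filter counts are free parameters; the reference
configuration uses (16, 32, 8, 8) and (64, 128, 32, 32) for its two
modules, chosen Inception-v1-proportioned so that the flattened 94 × 256
output against the published 200/150/100/50 dense stack lands the total at
4,905,431 trainable parameters (≈5 M).  The dense head applies dropout
before each layer (reference rates 0.54/0.33/0.10/0.46); widths must not
grow and may not fall below half their dense predecessor (the published
"aggressive reduction" with its stated floor).  All conv/dense kernels carry
an ℓ2 penalty (default 10⁻⁴) and truncated LeCun-normal initialisation
(sd = √(1/fan_in), resampling beyond 2 sd); batch norm contributes a
trainable scale and shift per channel (momentum 0.99, ε = 10⁻³).  The
feature map handed to the SVM is the post-activation output of the last
dense layer (50-wide in the reference model).

The network, including backpropagation through convolution, batch norm,
pooling and dropout, is implemented directly in numpy (`cnsvm.nnet`); the
analytic parameter count in `count_parameters` is checked in the tests
against enumeration of the instantiated weight arrays.

### Training

Stratified 70:30 train/validation split (train share = floor(0.7·n),
per-class quotas by largest remainder; a patient-grouped split is available
when patient ids are present, since the original protocol is unstated on
this point).  Loss is binary cross-entropy on the sigmoid output — the
publication names MSE only as an *evaluation* metric and never states the
training loss, and cross-entropy is the standard choice for a sigmoid
classifier; squared error on the sigmoid output is available behind
`loss="mse"`.  Inputs are z-scored per channel using training-partition
statistics only, stored on the model handle and reused at inference
(`standardize=False` restores raw percent input).  Optimisers: vanilla SGD
(no momentum) or Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷).  The learning rate
follows the Triangular2 cyclic schedule per iteration: with cycle =
⌊1 + t/(2s)⌋ and x = |t/s − 2·cycle + 1|,
lr(t) = base + (max − base)·max(0, 1 − x)/2^(cycle−1).  The step size s is
given in epochs (common CLR practice) and converted to iterations via the
batch count; pass `clr_step_in_epochs=False` to use iterations directly.
The published regime is 400 epochs at batch 128; the package default is 50
epochs, which is also the problem size used by the stochastic end-to-end
tests so the suite runs on one CPU in minutes.

### SVM head

Features are extracted with dropout off and batch norm in inference mode,
and a scikit-learn SVC (linear / polynomial / radial) is fitted on them;
the backbone stays frozen.  The reported tuning score is mean accuracy over
seeded stratified 10-fold cross-validation; the final head refits on all
features.  Because an SVM emits unbounded decision values, a Platt-style
logistic regression of decision values against labels supplies scores in
[0, 1] so ROC/AUC and MSE remain computable for the hybrid; predicted
labels come from the decision sign, with a value of exactly zero mapped to
the healthy class.

### Hyperparameter search

Tree-structured Parzen Estimator with expected-improvement selection, in
the cited algorithm's canonical settings: 10 startup trials from the prior,
good/bad split at the γ = 0.25 quantile of the objective (larger is
better), 24 candidates per suggestion drawn from the good density and
scored by the good/bad density ratio.  Continuous and integer dimensions
use Gaussian kernel densities with Silverman bandwidth
(0.9·min(sd, IQR/1.34)·n^(−1/5)), samples clipped to the bounds;
log-uniform dimensions are modelled on the log scale; categorical
dimensions use add-one-smoothed frequencies.  The bandwidth is floored at
1% of each dimension's range: with a collapsed bandwidth the search freezes
on a tight cluster of near-identical observations before the cluster has
drifted onto the optimum, and the floor keeps per-iteration proposals wide
enough to keep improving.  Failed (non-finite) trials are recorded but
excluded from density fitting.  Backbone and head are tuned sequentially
(backbone first), matching the workflow's narrative order.

### Evaluation

Accuracy, sensitivity, specificity (BCC = positive class; a rate with an
empty denominator is reported as absent, never as 0), ROC/AUC (thresholds
over the distinct scores, positive when score ≥ threshold; AUC by midranks,
i.e. P(score₊ > score₋) + ½·P(tie)), Cohen's κ
((p_o − p_e)/(1 − p_e), with the degenerate p_e = 1 defined as 0), and MSE
of the calibrated scores.  Quality flags follow the published reading:
AUC ≥ 0.8, κ ≥ 0.8, and |sensitivity − specificity| ≤ 0.1 ("balanced").
Segmentation crops every cube pixel to the window, standardises with the
stored training statistics, predicts with the hybrid model and reassembles
per-pixel labels and scores in row-major order.

## Synthetic data

The generator emulates the statistical structure the classifier must cope
with, not skin optics (no chromophore absorption model):

* **Baselines.** Healthy skin follows a smooth sigmoidal reflectance rise
  through the red/NIR (20–55%); the tumour mean equals it outside the
  window and sits `effect_size` percent lower at the window centre, the
  difference tapering to zero by a cosine ramp over the outer 10% of the
  window — smooth, so small receptive fields cannot key on an artificial
  discontinuity.  Healthy is the brighter class, matching the observation
  that lower reflectance is what separates tumour from healthy skin.
* **Patient effects.** A scalar offset per patient, drawn once and shared
  by all of that patient's signatures (round-robin assignment), the
  simplest structure exhibiting inter-patient variability while keeping
  parameter recovery checkable.
* **Noise and shadows.** Additive i.i.d. per-channel Gaussian noise, and
  with probability `shadow_prob` a multiplicative illumination factor
  drawn uniformly from `shadow_range` scaling the whole spectrum — the
  failure mode by which shadowed creases of a face mimic tumour.

Defaults are the study conditions where stated — 504 BCC / 488 healthy
signatures, 41 patients, the sensor grid and window above — and calibration
choices elsewhere: effect_size 6% (a moderate separation relative to the
baseline curves), patient_sd 1.5%, noise_sd 1.0%, shadow_prob 0.1 with
factors in [0.5, 0.95].  The published sensor description (260 channels at
2.2 nm from 398.08 nm) is internally inconsistent with its stated upper
bound (398.08 + 259·2.2 = 967.88 ≠ 995.20 nm); the implementation trusts
file headers when reading real data, and the synthetic grid ends at
967.88 nm.

What passing tests on this generator do **not** show: robustness to real
inter-patient spectral shape variation (the offset is a scalar, not a shape
change), to wavelength-dependent illumination, or to annotation noise in
clinical ROIs.  The published test-set numbers for the clinical data
(radial head: accuracy 0.91, κ 0.81, AUC 0.91) are stochastic reference
values from data this package cannot ship, not targets its tests assert.

## Numerical and design choices

* Window inclusion is closed on both ends; a 10⁻⁹ nm guard absorbs float
  jitter in reconstructed grids.  Wavelength headers are reconstructed as
  start + k·spacing (spacing from the first two headers) with 0.01 nm
  tolerance.
* Reflectance stays in percent through all I/O; standardisation happens
  only inside training, from the training partition.
* CSV round-trips write float64 at 17 significant digits and parse with
  round-trip precision, so table I/O is exact; ENVI cubes are written as
  float64 BIP with wavelengths in the header, so cube round-trips are
  bit-identical.
* Determinism: every stochastic component (simulation, weight
  initialisation, shuffling, dropout, fold assignment, TPE) flows from an
  explicit integer seed; repeated runs are identical on a single CPU.
* Degenerate inputs: empty class in a split, fold count exceeding the
  smallest class, unlabelled data reaching training, windows missing the
  grid, non-finite losses — all raise typed errors rather than proceeding.
* The compact test architecture (one inception module (8, 16, 4, 4), dense
  64/32) is the package's own choice of problem size for the stochastic
  end-to-end checks; the reference architecture is used wherever the check
  concerns architecture itself (parameter accounting).

## Known limitations

* The numpy backbone is single-threaded and CPU-bound; the reference
  architecture trains, but the published 400-epoch regime on it is slow
  compared to a GPU framework.  The package targets methodological
  fidelity, not throughput.
* The SVM head is binary; the multi-class extension (e.g. adding cutaneous
  squamous cell carcinoma) is out of scope.
* Platt calibration is fitted on the training features; on very small or
  perfectly separated samples its scores saturate near 0/1, which inflates
  MSE's optimism.  How the original experiments computed MSE for SVM
  outputs is unstated.
* TPE here is sequential only; no parallel or multi-objective search.
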