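# Methods

`semgst` classifies hand gestures from multi-channel surface electromyography
(sEMG). A continuous recording is reduced to a sequence of small images —
"matrix signals" — by windowing the signal, collapsing each window of each
electrode to one scalar feature, and arranging those scalars on the physical
electrode grid. A vision-transformer-style network (the *signal transformer*)
then classifies each image. This note documents the model, the parameters
that matter, the synthetic data generator, and the numerical and design
choices a maintainer should know about.

## Signal model and preprocessing

Input is a time × channels array in mV with per-sample gesture labels
(0 = rest) and 1-based repetition (trial) indices, read from HDF5, CSV or
MATLAB Level-5 containers (NinaPro-style key names `emg`,
`stimulus`/`restimulus`, `repetition` are understood; 10-channel/100 Hz and
128-channel/1000 Hz grid layouts are predefined).

Preprocessing, in order:

1. **Rest downsampling.** Acquisition protocols pause for ~3 s after every
   movement, so rest dominates the label distribution roughly 2:1. We keep
   every gesture-labeled sample and, of the rest blocks, only the single one
   immediately following the first gesture block; a keep-every-k-th-rest
   option exists for sensitivity checks. An index map back to the original
   sample positions is returned so provenance is never lost.
2. **Filtering.** Zero-phase (forward–backward) Butterworth low-pass,
   order 4. Default cutoff is `min(450, 0.45·fs)` Hz — 45 Hz for 100 Hz
   recordings, 450 Hz for 1000 Hz recordings — covering the useful sEMG band
   while respecting Nyquist. Zero-phase application avoids shifting the
   signal against its label stream.
3. **Rectification and amplitude normalization** (both optional, off by
   default): full-wave |x| or half-wave max(x, 0); division by a per-channel
   reference amplitude, with "auto" meaning the per-channel rectified
   maximum. They are off by default because the spectral and wavelet
   features below operate on the signed signal.
4. **Segmentation.** Overlapping windows of 320 ms with 100 ms overlap
   (32-sample windows, 10 overlapped samples at 100 Hz). Millisecond
   values are converted to samples with round-half-up so that 320 ms at
   100 Hz is exactly 32 samples. Windows start at multiples of the step;
   an incomplete trailing window is dropped. Each window is labeled by the
   majority vote of its per-sample labels (ties go to the smaller class id)
   and carries the majority trial index of the winning class.

## Features

Each window × channel is collapsed to one scalar; three pathways:

* **raw** — root-mean-square amplitude.
* **fft** — magnitude spectrum |Σₙ x[n]·e^(−j2πkn/N)|, aggregated as the
  mean magnitude over bins 1..N/2. The DC bin is excluded so baseline
  offset does not dominate the feature; this is configurable.
* **cwt** — continuous wavelet transform,
  c(a, b) = a^(−1/2) Σ_t s(t)·ψ((t−b)/a), against the Morlet
  ψ(t) = e^(−t²/2)·cos 5t or Mexican-hat
  ψ(t) = 2/(√3·π^(1/4))·e^(−t²/2)·(1−t²) mother wavelet, aggregated as the
  mean absolute coefficient over scales and shifts. Default scales are the
  integers 1..10 with the Mexican hat (scale 0 is undefined, so ranges
  quoted as "0 to 10" start at 1). The 1/√a prefactor is the standard
  energy normalization; a literal `a·` variant is exposed behind a flag for
  comparison. The wavelet is sampled on the signal's grid with support
  truncated at |t/a| ≤ 8, where both mother wavelets are below 1e-13;
  samples outside the window are treated as zero. The implementation is
  verified against a brute-force convolution oracle to 1e-6 relative and
  cross-checked against PyWavelets (which uses a different discretization,
  so agreement there is ~1%-level, not exact).

The aggregation function that collapses a window (or its spectrum /
scalogram) to one scalar is a declared default, not a canonical choice;
alternatives can be swapped in via the frame objects.

## Matrix signals

The length-C feature vector is placed on the electrode grid (2×5 for a
10-electrode band, 8×16 for a high-density array) in row-major order; an
arbitrary electrode-to-cell permutation is configurable, since physical
electrode layouts differ between setups. The grid is upsampled to 72×72
with bilinear interpolation (constant inputs stay constant; output range is
bounded by the input range) and normalized. Two normalizations are
provided: min-max to [0, 1] and z-score; a constant matrix maps to all
zeros under either. **Per-matrix z-score is the pipeline default**: the
transformer below is trained with a deliberately small step budget, and a
large common positive offset in the inputs (which min-max leaves in place)
measurably slows early training — on the reference synthetic cohort it is
the difference between ~72% and ~95% single-subject test accuracy at
identical hyperparameters. Dataset-level statistics can be supplied so the
training split's statistics are reused on the test split.

Augmentation (training split only): horizontal flip with probability 0.5
and rotation uniform in ±15° about the center, bilinear resampling with
edge padding, driven by an explicit seeded generator.

## The signal transformer

A standard pre-norm ViT over matrix signals:

* patches: P = 6 on a 72×72 image → N = 144 patches, flattened row-major
  (lossless: reassembly reproduces the image exactly);
* embedding: z₀ = [x_class; x_p¹E; …; x_pᴺE] + E_pos with learned
  E ∈ R^(P²C×D), CLS token and per-position embeddings (N+1 rows);
* encoder, L layers: z'ₗ = MSA(LN(zₗ₋₁)) + zₗ₋₁ and
  zₗ = MLP(LN(z'ₗ)) + z'ₗ, with multi-head softmax attention
  (scores scaled by 1/√(D/heads)) and a GELU MLP of width `mlp_ratio·D`
  (default 4);
* head: LN of the final CLS token, then an MLP with hidden sizes
  2048 → 1024 (GELU) and a softmax over classes.

Defaults: L = 8 layers and 8 heads (the full-scale configuration quotes
"8" for both and they are independently configurable), dropout 0.1 after
the attention projection and the MLP block, embedding width D = 64 (a free
parameter; the desk-size experiments use D = 32, 2 layers, 4 heads and a
128 → 64 head).

Implementation: pure NumPy, with hand-written backpropagation. Gradients
are exact and are verified against central finite differences in the test
suite. Dropout uses an explicit `numpy.random.Generator`, so training is
bit-reproducible given the seed.

Initialization: embeddings (E, E_pos, CLS) truncated normal, sd 0.02;
linear maps Xavier-uniform; LayerNorm gains 1, biases 0; the final logit
layer is **zero-initialized**. Two of these are load-bearing at the small
step budgets used here: Xavier-scale attention weights make attention
non-uniform at initialization (with tiny weights every query–key product is
≈0, attention is uniform, and the CLS token sees only the image mean —
class information never reaches the head); and the zero logit layer makes
the model start exactly uniform, so early updates follow the learned signal
rather than fighting random-init logit noise.

Training: AdamW (β = 0.9/0.999, decoupled weight decay applied to weight
matrices only), constant learning rate. Standard hyperparameters: batch 55,
8 epochs, learning rate 1e-4, weight decay 1e-4, evaluation hook every 100
steps. Cross-entropy loss. One model is trained per subject (pooled
training is available).

## Evaluation protocol and metrics

Two split protocols, both keyed on the trial index so train and test never
share a repetition: the 7/3 repetition split (train on repetitions
{1, 3, 4, 6, 8, 9, 10}, test on {2, 5, 7}) and the odd/even trial split.
Windows whose majority label is rest carry trial index 0 and belong to
neither split. Metrics — accuracy, macro F1, micro F1, all in percent — are
computed from the confusion matrix and averaged unweighted across subjects.
Conventions: a class absent from both truth and prediction contributes
F1 = 0 to the macro average (the strictest reading; it changes numbers on
imbalanced sets), and for single-label problems micro F1 is identically
equal to accuracy — the test suite asserts this identity on random
confusion structures.

## Synthetic data generator

Each subject's recording is
`gain · A[class, channel] · envelope(t) · carrier(t, channel) + noise`,
where the carrier is white Gaussian noise band-passed to 20–min(450,
0.45·fs) Hz (renormalized to unit variance so band choice does not change
power), the envelope is a raised cosine with 10% onset/offset ramps so
windows straddling block boundaries are realistic, A is a class × channel
activation map in [0, 1], the subject gain is log-normal
(`exp(subject_gain_sd · z)`), and the additive noise has sd `noise_sd` mV.
The label stream is: initial rest, then each gesture followed by a rest
pause, cycling through all classes once per repetition. Defaults: 10
channels at 100 Hz, 4 gesture classes × 10 repetitions, 5 s gestures, 3 s
rests, noise sd 0.05 (high SNR against a unit-variance carrier), subject
gain sd 0.1. Noise and subject gain come from independent seeded streams,
so a subject is reproducible inside any cohort.

What the generator does *not* emulate: motor-unit recruitment and firing
statistics, electrode-skin impedance and contact artifacts, power-line
interference, fatigue drift, inter-channel crosstalk beyond the activation
map, or electrode-shift between sessions. Passing the end-to-end tests
therefore shows that the pipeline recovers class structure of this
idealized form — patterns of per-channel amplitude — not that the reported
full-scale accuracies on real databases are reproduced.

## Reference experiments and problem sizes

Two canonical experiments (in `semgst.experiments`) are sized to run on a
single CPU core in minutes:

* **cohort experiment** — 3 subjects of the default generator (≈920
  windows/subject after rest downsampling; ≈635 train / 273 test windows
  per subject), CWT features, scaled-down transformer (D = 32, 2 layers,
  4 heads, 128→64 head), standard learning rate/weight decay and 8 epochs,
  7/3 repetition split, per-subject models; reports cross-subject mean
  accuracy and F1. One deviation from the full-scale recipe: batch size 8
  instead of 55. With ~635 training windows, 8 epochs at batch 55 give
  the optimizer fewer than 100 steps at lr 1e-4 — not enough to separate
  the hardest class pair (the two classes that activate only two
  electrodes each, at grid positions that are translations of one
  another); measured per-subject accuracies move from 94/74/72% at
  batch 55 to ≈95/99/97% at batch 8, with dropout changes having no
  effect — the failure is step count, not regularization.
* **attention experiment** — one subject whose activation map makes only
  electrodes 2 and 7 class-informative (all other channels share a constant
  amplitude across classes). After training, attention rollout from the
  CLS token — head-averaged attention mixed with the identity,
  renormalized, multiplied across layers — measures the attention mass on
  the patches covering the informative electrodes, compared with the
  uniform share. Two design points make this a valid localization probe:

  1. Matrix signals are normalized with *training-split* z-score
     statistics, not per-matrix statistics. A per-matrix statistic
     depends on the informative channels' amplitudes, so dividing by it
     copies class information into every background pixel; the model can
     then classify from any patch and measured attention stays uniform
     (≈1.1× the uniform share).
  2. The probe model has a single encoder layer with a single attention
     head, trained without dropout at a higher learning rate and for more
     epochs than the cohort experiment (localizing attention requires
     actually moving the attention weights). With one layer, the CLS
     attention row is exactly where class information must enter the CLS
     token; with two layers the information can hop via intermediate
     tokens and the identity-mixed rollout dilutes toward uniform (≈1.3×)
     even with fixed normalization. With several heads, averaging dilutes
     a localizing head with near-uniform ones (≈1.5–2.2× across seeds,
     versus ≈3× single-head).

## Numerical notes and limitations

* Round-half-up ms→samples conversion is deliberate: banker's rounding
  would map some window/rate combinations off by one sample.
* `filtfilt` edge transients are real; attenuation properties are asserted
  away from window edges in the tests.
* The micro-F1 = accuracy identity holds only for complete single-label
  prediction; reported micro-F1 values that differ from accuracy imply a
  different (multi-label or incomplete) metric computation.
* Training the full-size model (D = 64, 8 layers, 2048→1024 head) on real
  multi-hour database recordings is supported by the code but is far beyond
  the scope of the bundled experiments; the loaders and splits exist so
  such runs are a data-download away.
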