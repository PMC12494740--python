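# Methods

## Scope and data model

The package operates on hypercubes `X ∈ ℝ^{y×x×λ}` of non-negative, finite
intensities on a uniform wavelength grid (`WavelengthAxis`: start, step,
channel count; the reference instrument is 1004 channels × 0.728 nm from
325 nm, a 731 nm span). Channel indexing is 0-based and windows are half-open
`[s, e)` with `e = s + w`, so slicing composes like Python slices. Input with
NaN/Inf is rejected at construction and at load time rather than imputed: the
method is explicitly aimed at raw, un-denoised data, and silent cleaning
would change what the selection criteria see.

Two file dialects are supported. ENVI pairs use BSQ interleave, little-endian
float32, and require a `wavelength` list in the header (round trips are exact
to single precision). The HDF5 container stores one float64 dataset `cube`
with `start_nm`/`step_nm`/`label`/`meta.*` attributes and round-trips
bit-exactly. No instrument control, calibration, or preprocessing is in
scope.

### nm ↔ channel conventions

A window width in nm converts to channels by round-to-nearest (half away from
zero), floored at 1: 20 nm / 0.728 nm → 27 channels. "Data-size reduction" is
the discarded fraction of *spectral channels* (spatial extents are
unchanged), so a 20 nm window on 1004 channels discards 1 − 27/1004 = 97.3 %.
Note the analogous channel-count accounting gives 93.1 % at 50 nm and 86.4 %
at 100 nm; alternative accountings that yield slightly different figures for
those widths exist, but the channel fraction is the definition used
throughout because it is exact, unit-free and matches the 20 nm case. A
wavelength *interval* maps to the covering channel interval
(floor start, floor end + 1, with a 1e-9-channel tolerance for endpoints that
sit on the grid).

## Selection criteria

All criteria produce one non-negative score per channel; window scoring and
argmax selection are shared and criterion-agnostic.

* **Standard deviation** — the population (divide by `y·x`) standard
  deviation of the band over all spatial pixels. Population, not sample: the
  band's pixels are the entire population of interest.
* **Mutual information** — the cube is reshaped to `(y·x) × λ`; the reference
  variable is the per-pixel mean across channels; both variables are
  discretised independently into `B` equal-width bins over each variable's
  own [min, max]; `I` is the plug-in estimate in bits, with empty joint cells
  contributing zero and any constant variable carrying exactly zero
  information (a degenerate case, not an error). Tiny negative round-off is
  clamped to 0.
* **Shannon entropy** — per band, the plug-in entropy in bits of the
  equal-width `B`-bin histogram of pixel intensities.

`B` defaults to 64: with 64×64 = 4096 pixels this gives ~64 samples per bin,
a reasonable bias/variance point for plug-in estimates, and it is
configurable (the invariance tests cover other values). Because binning is
range-relative, `H` and `I` are invariant under strictly increasing affine
rescaling of intensities; `σ` scales linearly. Logarithms are base 2
throughout.

The sliding window moves with stride 1 over all `n − w + 1` starts; the
cumulative score is a prefix-sum difference; argmax ties resolve to the
smallest start (deterministic and order-independent). The random baseline
draws the start uniformly from the admissible range with its own seed and
skips scoring entirely.

**Dataset-level selection** computes the score vector per cube, averages the
vectors (unweighted) across cubes, and takes one global argmax. The
aggregation had to be chosen (mean, sum and pooled-pixel scoring are all
defensible); the unweighted mean was picked because it is scale-stable as the
dataset grows and reduces to single-cube selection for identical cubes. With
equal cube counts per class, mean and sum select identical windows.

Window widths below 20 nm are allowed by the API but the CLI warns: on raw
instrument data, narrow high-noise regions near the spectral edges (roughly
950–1050 nm on the reference instrument) can out-score genuine features.

## Synthetic data generator

The generator emulates the regime of H&E-stained organ-tissue microscopy
where all classes look alike except in one wavelength region:

* **Signatures**: all classes share a smooth quadratic baseline
  (0.9 + 0.2t − 0.2t² on the normalised axis coordinate, ±5 % variation);
  each signal class adds two Gaussian peaks (default amplitude 0.5 and 0.3,
  width 6 nm at full scale) whose centres are laid out on an interleaved grid
  strictly inside the informative window (margin 3×width keeps tails inside),
  with a small seeded jitter. The last class is always a baseline-only
  background. Outside the window, pairwise class differences are only Gaussian
  tails, below 10 % of the in-window contrast.
* **Texture**: a per-cube multiplicative amplitude field
  `A = 1 + texture_amp · G`, `G` a unit-variance Gaussian field smoothed to
  correlation length `texture_scale` pixels (default 0.15 and 4). Multiplicative
  rather than additive because stain-density variation scales the whole
  spectrum of a pixel — and because it yields the closed form
  `σ_λ = std(A) · signature(λ)` in the noiseless limit, which the tests
  exploit as an analytic oracle.
* **Noise**: i.i.d. Gaussian per voxel with per-channel scale
  `base_sigma · (1 + (edge_factor − 1) · ramp)`, the ramp rising linearly
  from 0 to 1 within `edge_width_nm` of either spectral end (defaults 0.02,
  3, 30 nm). This emulates detector roll-off at the band edges — the reason a
  20 nm window floor is recommended — without claiming to reproduce any real
  instrument's noise law. Values are clipped at zero after noise; with the
  default amplitudes the clip is essentially inactive (it would need a >5σ
  texture excursion), so the analytic σ identity holds to float precision.

Defaults follow the reference design: 11 classes × 100 cubes of 64×64×1004
channels, informative window 470–570 nm (channels [199, 337)). The
desk-scale `test_profile` — 5 classes × 10 cubes of 32×32×200 channels
spanning 325–471 nm, window 390–420 nm, peak width 3 nm — is the default for
the test suite and benchmark; it keeps the full 100-seed recovery study and
the 10-run training benchmark at a few minutes on one CPU while preserving
the full-scale profile's relative geometry.

What passing tests on this generator do **not** show: robustness to real
stain variability, optical PSF, scanner line artifacts, non-Gaussian noise,
or classes whose differences are spread across many disjoint regions. They
do show that the selection machinery finds a genuinely informative contiguous
region when one exists and that the comparison harness orders methods
correctly under a known ground truth.

## Classifier and protocol

The network is conv(3×3, F1, pad 1) → ReLU → maxpool(2, stride 2) →
conv(3×3, F2, pad 1) → ReLU → maxpool → flatten → FC(512) → ReLU →
FC(n_classes), with spectral channels as input feature channels — so band
selection changes only the first convolution's input arithmetic. Filter
counts default to (16, 32), the smallest common doubling scheme, and are
configurable (the desk-scale benchmark uses (8, 16)). The implementation is
plain numpy (im2col convolutions, hand-written Adam) in float64: the models
are tiny, and full determinism given the seed is worth more here than
throughput. Gradient correctness is verified against central finite
differences in the test suite. 'Same' padding keeps each pool stage an exact
halving (floor for odd extents); max-pool ties take the first maximum.

Training: softmax cross-entropy, Adam starting at 1e-4 with exponential decay
0.95 per epoch (a schedule had to be fixed; exponential is the simplest
monotone choice and is configurable), batch size 2, early stopping after 15
consecutive epochs without a new validation-loss minimum, best-epoch weights
restored afterwards. Divergence (non-finite loss) raises an error naming the
epoch.

Splitting is stratified 80/20 train/test (880/220 on the 11×100 design —
plain random splitting would give the same sizes but could starve a class),
with a 10 % validation carve-out from the training portion. Early stopping
monitors this held-out validation set, never the test set; the carve-out
falls back to unstratified when it is smaller than the class count.
Normalisation is global min–max to [0, 1] computed on the training portion
only. Both the best-epoch and final-epoch test accuracies are recorded; the
comparison tables use the best-epoch value because that is the state early
stopping selects.

`run_comparison` runs each method over `n_runs` seeds (seed = master + run
index). The window is selected on the training portion (train + validation)
only, never on test cubes — verified by a leakage test that recomputes the
window. Epoch wall-times are recorded for information only; they are
hardware-dependent and never part of any assertion.

## Benchmark problem sizes

The standing benchmark (`benchmark_comparison`) uses the desk-scale profile
with a 12-epoch budget, patience 5, (8, 16) filters and learning rate 3e-4 —
sizes chosen so a 2×10-run comparison completes in minutes on a single CPU
while leaving a clear accuracy gap between structured and random selection.
The 100-seed planted-window recovery study uses the same profile. These sizes
are the package's fixed benchmark conditions; scaling up to the full 11×100 ×
64×64×1004 design is a matter of configuration, not code.

## Known limitations

* Exactly one contiguous window is selected; disjoint band subsets (mRMR-style)
  are out of scope.
* The MI/entropy estimators are plug-in histogram estimates with no bias
  correction; they are used for *ranking*, where the shared bias matters
  little.
* The numpy CNN is single-threaded-friendly but slow at full 64×64×1004,
  11×100 scale; the full-scale run is possible but not routine.
* The synthetic generator's qualitative realism (similar spectra, edge noise)
  is designed-in, not fitted to measured tissue data.
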