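# Methods

## Problem and scope

`specnet` implements a multimodal convolutional-network approach to
classifying near-infrared (NIR) spectra of plant material by geographic
origin.  A sample's diffuse-reflectance NIR spectrum — 1609 absorbance
values on a 4000–10000 cm⁻¹ wavenumber grid — reflects overtone and
combination vibrations of its chemical bonds, and origin-related
compositional differences appear as subtle changes in broad, overlapping
absorption bands riding on a drifting baseline.  The package provides three
classifiers over such spectra:

1. a parameterised family of **1-D CNNs** acting directly on the spectrum;
2. a **2-D CNN** (LeNet-5 variant) acting on a square image obtained by
   row-major reshaping of a spectrum prefix;
3. a **PLS-DA** linear baseline on the low-wavenumber feature segment.

The real tobacco spectra that motivated this design are proprietary, so the
package ships a synthetic-spectra generator that emulates the study design
(13 origin classes C1–C13, 400 samples per class, 320/80 train/test split,
three replicate scans averaged per sample) and gives every stage a
controllable, reproducible test bed.

## Synthetic spectra generator

Each class template is a sum of

* `shared_band_count` (default 6) Gaussian absorption bands common to all
  classes, amplitudes 0.2–1.0 absorbance units, widths 60–250 cm⁻¹;
* `bands_per_class` (default 4) class-specific Gaussian bands, amplitudes
  0.05–0.30 scaled by the `separability` factor;
* a smooth global baseline rising toward low wavenumbers, as in
  diffuse-reflectance NIR.

A sample adds a per-sample linear baseline drift (slope and offset s.d.
0.05) and i.i.d. Gaussian noise (s.d. 0.01) per replicate; the stored
spectrum is the mean of `n_replicates` (default 3) replicates.
`separability = 0` collapses every class onto the shared template, giving a
pure chance-level control.  Band parameters for class *k* are drawn from a
stream keyed by (seed, *k*), so extending the class set never perturbs
earlier classes, and a fixed seed yields byte-identical datasets.

`band_sign_flip` produces a deliberately **nonlinear** class structure: the
class-specific component of each sample is multiplied by an alternating ±1,
exactly half the class each way.  Class means then coincide — a linear
classifier on the raw features is reduced to chance — while class identity
is still carried by *where* the spectral energy sits, which rectifying
(ReLU) networks can detect.  This is the regime used to demonstrate the
CNN-over-PLS-DA ordering.

What the generator does **not** emulate: Fourier-transform instrument
physics, water-vapour lines, scatter effects (no MSC/SNV is needed or
implemented), or real tobacco chemistry.  Passing tests therefore show that
the pipeline recovers known structure of this band-model family, not that
any accuracy figure transfers to real tobacco spectra.

### Grid

The grid is `linspace(4000, 10000, 1609)` (spacing ≈ 3.73 cm⁻¹).  The
nominal instrument resolution of such spectrometers (8 cm⁻¹) is not a grid
spacing; the 1609-point count is load-bearing for every downstream shape
(1600 = 40², 1024 = 32²) and governs.

## Preprocessing

First derivative with Savitzky-Golay smoothing, window 9 points, polynomial
order 3, applied as a **single joint S-G convolution** with `deriv=1` (the
standard chemometric formulation) rather than difference-then-smooth.  The
derivative is taken with respect to wavenumber (units absorbance·cm), using
the uniform grid spacing.  Edges are handled by fitting the local
polynomial on the one-sided window (scipy's `mode="interp"`), so the output
length equals the input length and no values outside the measured range are
fabricated.  The filter is exact for polynomials up to order 3, removes
constant baseline offsets exactly, and maps linear drift to a constant.

## Network core

The numerical core is written in numpy with explicit forward/backward
passes, verified against nested-loop oracles and finite-difference
gradients:

* **Convolution** is cross-correlation (no kernel flip), stride 1, valid
  padding: a length-L input and width-m kernel give L−m+1 outputs.
* **ReLU** activations throughout.
* **Pooling** is non-overlapping (stride = width) max pooling by default;
  average pooling is available.  When the post-convolution length is not
  divisible by the pool width, the trailing remainder is dropped and a
  warning logged — preferred configurations divide exactly.
* **Softmax + categorical cross-entropy** at the output.  The loss
  gradient is `(softmax(logits) − onehot)/batch`.
* **Dropout** (p = 0.5 on fully connected layers, training mode only) uses
  the inverted formulation, so evaluation needs no rescaling.
* **Weight initialisation**: seeded uniform(−1, 1)/√fan_in ("small random
  numbers"); biases zero.

### Training protocol

Plain mini-batch SGD, no momentum: learning rate 0.01, batch size 40, at
most 50 epochs.  Early stopping implements the turn-up rule: training ends
when the monitored error has not improved for `early_stop_patience` epochs
(default 5) and the weights of the best epoch are restored.  The monitored
set is by default a carved-out 12.5 % validation subset of the training
split; `monitor="test"` reproduces protocols that watch the test error
directly (with the leakage that implies).  The cross-entropy loss and the
absence of momentum are package choices; a protocol that states only
"gradient descent" admits both.

Inputs to the 1-D CNN are standardised **per wavenumber** using training
split statistics: derivative spectra are numerically tiny (∼10⁻⁴) and their
scale varies strongly along the axis, and with global scaling the quiet
spectral regions that carry class information are invisible at learning
rate 0.01.  The 2-D CNN standardises per pixel for the same reason (each
pixel is a fixed wavenumber).

## 1-D CNN family

Depth D = 2·n_stages + 3 counts hidden layers plus the output layer: each
stage is conv + pool, then two fully connected layers and the 13-way softmax
output.  All stages share one conv width, pool width and feature-map count
M — exactly the three knobs the sweep drivers vary (depth 5–13; conv width
3, 5, …; pool width 1–5 including identity pooling; maps 6, 12, 18, …).
FC1 has as many nodes as the flattened feature length; FC2 equals FC1.  The
reference configuration is depth 11 with conv 1×15, pool 1×2, M = 24, whose
length trace on 1609 points is
1609 → 1595 → 797 → 783 → 391 → 377 → 188 → 174 → 87 (FC1 = 87·24 = 2088).

## Spectral images and the 2-D CNN

A spectrum prefix of n² points is reshaped row-major into an n×n image:
points 1..n form row one, n+1..2n row two, and so on.  The full 1609-point
spectrum drops its last 9 points to give 40×40; the first 1024 points
(4000 up to ≈7740 cm⁻¹, the high signal-to-noise feature segment) give
32×32.  Shrinking the side in steps of 2 down to 26 truncates further from
the high-wavenumber end; the retained endpoint is always read off the grid
rather than hard-coded.  Pixel values are the preprocessed derivatives,
min-max scaled to [0, 1] over the dataset.

The 2-D model is the classic LeNet-5 topology — 6 then 16 feature maps of
5×5 kernels with 2×2 pooling, then 120- and 84-unit fully connected layers —
with a K-way softmax head, ReLU activations and max pooling (the modern
variant; the original's tanh/average-subsampling is not used), and the
flatten size recomputed for any input side ≥ 18.  After full training the
fully connected classifier can be re-initialised and re-fit with the
convolutional trunk frozen (`refit_head=True`, the default), i.e. the
trunk's features train a brand-new classifier.

## PLS-DA baseline and embeddings

PLS-DA is PLS2 regression of the mean-centred feature-segment matrix (first
1024 points) on the one-hot class-indicator matrix with 7 latent variables,
predicting by argmax over the fitted indicator responses (ties toward the
lower class index).  The regression engine is scikit-learn's NIPALS
`PLSRegression`; the first weight vector is verified in the tests against
an independent SVD oracle (dominant singular direction of XᵀY).  "7
components" is read as 7 latent variables.

PCA and t-SNE 2-D views (t-SNE: perplexity 30, 1000 iterations, PCA
initialisation, seeded) are provided for class-separability inspection.

## Evaluation

Accuracy is P_A = 100·N_C/N_T percent; confusion matrices are K×K integer
counts with rows = true class, columns = predicted class, and per-class
accuracies are row-normalised diagonals.  Reported accuracies are rounded
to 2 decimals.  `compare_models` trains the three classifiers on one
preprocessed dataset under a shared seed and reports the three test-set
accuracies and confusion matrices.

## Problem sizes and numerical choices

* Unit tests run on short grids (101–401 points) with 3–4 classes, which
  exercises every code path in seconds.  End-to-end runs (acceptance tests
  and `scripts/acceptance.py`) use the full 1609-point grid with 13 classes
  at 50 samples per class (40/10 split per class), the package's chosen
  desk-scale rendition of the 400-per-class design.
* Network parameters are float32 for training speed; oracle and
  gradient-check tests build float64 layers (loop-oracle agreement < 1e-10,
  finite-difference relative error < 1e-4).
* On the nonlinear sign-flip data the validation error plateaus for a few
  epochs before the network takes off, so the comparison runs use
  early-stop patience 15 instead of the default 5; all other protocol
  values are unchanged.
* Seeding: one top-level integer seed; every consumer (band parameters,
  sample noise, weight init, batch shuffling, dropout, validation carving)
  derives an independent stream via `SeedSequence` spawn keys, so runs are
  bit-reproducible and adding consumers does not disturb existing streams.

## Known limitations

* The generator's band model is not calibrated to tobacco chemistry; no
  public reference spectra exist to calibrate against.  Absolute accuracy
  figures on synthetic data say nothing about accuracy on real spectra.
* Plain SGD without momentum or scheduling converges slowly on hard
  nonlinear structure; the training protocol is kept deliberately simple
  rather than competitive.
* The full >200-architecture grid search behind the reference
  configuration is out of scope; the sweep drivers reproduce its axes at
  configurable scale.
* Pooling with remainder truncation discards up to w−1 trailing points per
  stage; configurations are validated so the preferred settings divide
  exactly.
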