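# Methods

## Forward model and conventions

A pixel of the sample is a 4×4 real Mueller matrix **M**; the instrument
prepares one of six generator states and analyzes with one of six analyzer
states (H, V, P, M, R, L), giving 36 scalar intensities
`I = ½ aᵀ M s`. Conventions, each held in a single constant so it can be
audited or flipped:

* **Handedness** — right-circular light carries s₃ = +1
  (`polarization.RIGHT_CIRCULAR_S3`). The literature is split on this
  convention and the source measurements do not pin it down; every quantity
  downstream of m11 normalization is invariant to flipping it consistently,
  so the choice is cosmetic.
* **Detector constant ½** — chosen so the four-term element combinations
  return exactly `2·m_rc`. Any global scale cancels under m11
  normalization.
* **Angles** — polarizer/wave-plate angles in degrees, counterclockwise
  from horizontal.

`random_physical_mueller` draws genuinely physical matrices as convex
mixtures of products of rotated polarizers, quarter-wave plates and
diagonal depolarizers. Because each factor maps physical Stokes vectors to
physical Stokes vectors, all 36 forward intensities of such a matrix are
nonnegative — which is what makes them valid oracles for the
reconstruction round trip and the combination-table check.

## Reconstruction

The canonical combination table is generated from the generator/analyzer
pair selectors (column: H+V, H−V, P−M, R−L; row likewise) and is validated
against the forward model: applied to the 36 intensities of any physical
matrix it must return `2·m_rc` for every element to 1e−10. An alternative
`as_printed` table reproduces a published variant whose m33 cell contains
an `MH` term where the self-consistent term is `MP`; `validate_table`
flags exactly that cell, and the CLI records the inconsistency in output
metadata when the variant is requested.

Normalization divides every element by m11 per pixel. Pixels with
`m11 ≤ 1e−6 × max(m11)` are masked invalid (never NaN) and excluded from
all statistics; a sample with no valid pixel raises a degenerate-sample
error. Normalization by the image-mean m11 instead of per-pixel is a
one-line change but per-pixel is the default, since it is the only reading
under which normalized elements are bounded by 1 pixel-wise. Optional
clipping of normalized elements to [−1, 1] is off by default; noise can
legitimately push estimates slightly outside the physical range and
silently clipping would bias cohort means.

Cohort element summaries average each element over a sample's valid pixels
first, then report mean ± std across samples (`pool_pixels=True` pools all
valid pixels instead; both modes exist because published summary tables do
not state which was used).

## MMT parameters

From the normalized central block and m44:

* `b = (m22 + m33)/2`, `t = √((m22 − m33)² + (m23 + m32)²)/2`,
  `Δ = 1 − (|m22| + |m33| + |m44|)/3`. These are typographically
  unambiguous and have a single implementation.
* **A** is exposed in two variants. The expression as typeset uses the
  radicand `(m22 − m33)² + (m22 + m33)²` and violates its own stated
  [0, 1] range (e.g. m22 = m33 = 0.5, m23 = m32 = 0 gives A = 2). The
  default `he2014_corrected` variant replaces the radicand with
  `(m22 − m33)² + (m23 + m32)²`, reducing to `2bt/(b² + t²)`; we take the
  magnitude of the numerator (`2|b|t/(b² + t²)`) so the [0, 1] range holds
  for every input, not only for media with b ≥ 0 — the two agree on all
  tissue-like matrices, where b > 0.
* **G** as typeset has the numerator `(m22·m33 − m22·m33)²`, which is
  identically zero, so G ≡ 1 wherever its denominator is nonzero. Because
  no corrected form can be confirmed from the source alone, `as_printed`
  remains the default and a `conjectured_corrected` variant (numerator
  `(m22·m33 − m23·m32)²`) is available. Every `MMTMaps` records the
  variants that produced it.

Pixels where A or G are undefined (zero denominators) are masked and the
mask propagates into all statistics.

## Synthetic phantoms

The generator emulates the layout of a transmission polarimetry dataset of
colorectal histology slides: per-sample directories of 36 images named by
the two-letter state code, a JSON manifest, and `train.txt`/`test.txt`
split lists (seeded, stratified by class).

Ground-truth fields use per-class template matrices taken from published
cohort element statistics (normal: m22 ≈ 0.2845, m33 ≈ 0.2818,
m44 ≈ 0.4667; cancer: m22 ≈ 0.1732, m33 ≈ 0.1743, m44 ≈ 0.4450, with the
published across-sample standard deviations). Per sample, one latent
standard-normal scalar shifts all elements coherently by their
across-sample spreads — modelling slice-to-slice severity variation —
and a zero-mean spatially smooth texture (Gaussian random field smoothed
at correlation length 8 px, amplitude 0.02 for the normal class; 0.03
diagonal / 0.05 off-diagonal for the cancer class, giving the malignant
class its stronger off-diagonal heterogeneity) is added per element.
Elements are clipped to [−1, 1] and m11 ≡ 1. The class contrast this
produces — lower m22/m33, lower b, higher Δ in the cancer class — is the
direction reported for real tissue.

Rendering maps full transmission to 200 detector counts (not 255, so
additive noise rarely clips), applies Gaussian (additive on counts) or
Poisson (on scaled counts) noise, and quantizes. `uint8` mode writes RGB
with the signal in the red channel, green identically zero and a faint
blue floor ≤ 4 counts, mirroring the color statistics of the He–Ne-laser
instrument; `float` mode writes single-channel float TIFFs and
round-trips the ground truth exactly (< 1e−9) through reconstruction.

What the phantoms do **not** model: optical aberrations, substrate
birefringence, vignetting, spatial structure of real glands, or any
texture statistics beyond second order. Passing tests therefore
demonstrate the correctness of the pipeline's algebra, bookkeeping and
statistics on data with the published first-order class contrast — not
classification performance on real tissue.

## Preprocessing

Red channel extraction (single-channel images pass through), center crop
(default 900×900; odd remainders go to the right/bottom), anti-aliased
bilinear resize to 224×224, scaling to [0, 1] by 1/255 from the count
domain, channels stacked PSG-major (`6·index(psg) + index(psa)`). The
resize kernel and the 1/255 scaling are configuration, not hard-coded,
since the source pipeline states only "rescaled".

## Statistics

* FDHs: pooled valid pixels per cohort on shared edges over [−1, 1]
  (default 100 bins), with peak locations per cohort.
* Two-cohort tests: Welch (unequal-variance) t for independent cohorts,
  paired t for aligned per-sample comparisons; star coding with ****
  for p < 0.0001.
* Metrics: accuracy, precision, recall, F1 with the cancer class positive;
  undefined ratios are reported as `None`, never as 0. Display rounding is
  half-up to 3 decimals; full precision is kept internally.
* McNemar: `χ² = (max(|n01 − n10| − 1, 0))²/(n01 + n10)` against χ²(1).
  The explicit floor at |n01 − n10| ≤ 1 keeps the continuity correction
  from producing a spurious positive statistic at equality.
* Exact binomial: doubled smaller tail at p = 0.5, capped at 1; the
  |n01 − n10| ≤ 1 case returns exactly 1 (the doubled tail already covers
  at least half the symmetric mass).
* `compare_models` prefers the exact binomial when n01 + n10 ≤ 10 and
  McNemar otherwise, and calls significance on the preferred p.

Both tests are conservative by construction. Exact enumeration under the
null used in our calibration check (two equal-accuracy classifiers,
n = 100, disagreement probability 0.2, α = 0.05) puts the preferred
test's true size at ≈ 0.027 rather than the nominal 0.05; simulated
rejection rates near 0.025 are the expected behavior of the
continuity-corrected test, not an implementation defect.

## Classifiers

Implemented entirely in numpy (im2col convolutions, analytic backward
passes verified against finite differences):

* `cnn`: per stage a 3×3 Conv + BatchNorm + ReLU + Dropout(0.2) block
  followed by 2×2 max pooling; widths default to (128, 256, 512); global
  average pooling; fully connected 512 → 256 → 1.
* `cnn_2`: the same widths with a stride-2 convolutional block replacing
  each pooling stage and a 1×1 convolutional head (→ 256 → 1) replacing
  the fully connected layers.

Dropout probability is fixed at 0.2; depth, widths, head width and input
size are configuration so the training loop can be exercised at desk
scale — the test suite and the acceptance script train at 32×32 input
with widths (8, 16, 32), which preserves every architectural property
being checked (block structure, head contract, optimization behavior)
at a fraction of the arithmetic. Training: AdamW (decoupled weight decay
0.001), binary cross-entropy on logits, batch size 16 (4 at desk scale),
up to 200 epochs, ReduceLROnPlateau (factor 0.1, patience 10) and early
stopping (patience 20) on validation loss; plateau/early-stop patience
values are not pinned down by the published protocol and are defaults
recorded in every history. All randomness (init, shuffling, dropout)
derives from a single seed; identical config and data reproduce the
identical loss history.

Channel inflation copies the 3 pretrained input channels bit-exact and
He-initializes the remaining 33 with the inflated layer's fan-in
(36·k²), seeded. An input whose extra channels are zero therefore
produces exactly the 3-channel layer's response.

Augmentations (rotation, CLAHE, blur) apply one spatial transform jointly
to all 36 channels — per-channel transforms would destroy the pixel-wise
registration that the element combinations rely on.

## Pipeline

One global seed is fanned out per stage via `numpy.random.SeedSequence`.
Every run writes a manifest with the fully resolved configuration and
package version; artifacts are only replaced under an explicit overwrite
flag; reports are byte-reproducible for identical config + seed (timings
go to the log, never into artifacts).

## Problem sizes

Defaults used by the test suite and acceptance script: phantoms 16–64 px
square (the full 1280×1024 instrument frame is supported), cohorts of 20
samples per class for direction-of-effect checks, 100 random matrices for
round-trip bounds, 2,000 simulations for test calibration, 8 phantoms for
the training smoke run. These sizes were chosen so the whole suite runs
in well under a minute of arithmetic while leaving every assertion's
statistical margin wide.
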