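# Methods

`eegmem` implements a pattern-recognition pipeline that predicts whether a
person answering a quiz question is recalling a true memory (they answer
correctly) or a false one (they answer incorrectly), from the EEG recorded
during the answer window.  The pipeline treats the EEG not as a set of time
series but as a movie of scalp images, and classifies questions by the
texture of those images.

## Pipeline

For each question the stages are:

1. **Preprocess.**  The continuous recording (M channels x T samples,
   microvolts; 250 Hz in the target protocol) is band-pass filtered to
   1-48 Hz with a 4th-order Butterworth applied forward-backward
   (`sosfiltfilt`), so the filter is zero-phase and topomap timing is
   preserved.  An optional channel keep-list drops electrodes (the target
   protocol keeps 93 of 128; the retained subset is configuration, since no
   canonical list exists).  The answer window `[start, end)` of each
   question is cut out using a half-open, 0-based sample convention so the
   epoch length is exactly `end - start`.

2. **Topomaps.**  Each time sample's potential vector is rendered as a 2-D
   scalp image: piecewise-linear interpolation on the Delaunay
   triangulation of the 2-D electrode positions, evaluated at the pixel
   centers of a `grid_size x grid_size` grid covering the head disc, with
   nearest-electrode fill between the triangulation hull and the disc edge.
   Linearity of the interpolator in the potential vector is a tested
   invariant.  Pixels outside the disc are masked and excluded everywhere
   downstream.  Pixel values stay in raw microvolts — no per-map
   normalization — so amplitude differences between classes survive into
   the mean features.  Default `grid_size` = 64 (divisible by both 8 and 16
   block tilings); a 30-s epoch at 250 Hz yields 7 500 maps.

3. **Selection.**  Consecutive maps are nearly identical, so the city-block
   (Manhattan) distance `d_t = sum |map_t - map_{t+1}|` over in-mask pixels
   is computed for every consecutive pair, pairs are ranked by descending
   distance (ties to the earlier pair, for determinism), and for the L
   top-ranked pairs the later member — the map that introduced the change —
   is kept, re-sorted into temporal order.  Keeping the earlier member
   instead is a documented switch (`pair_keep`).  Only consecutive pairs
   are considered: the step removes temporal redundancy, and an all-pairs
   variant would cost O(T^2) distances per question.

4. **Features.**  Each selected map is tiled into `B x B` blocks (B = 8 or
   16; blocks tile the full grid, and fully masked corner blocks emit zeros
   so the dimension is constant).  Per block, up to five first-order
   statistics of the in-mask pixels are computed in the fixed order mean,
   standard deviation, entropy, skewness, kurtosis; an integer "number of
   features" setting means a prefix of that order.  Conventions: population
   (n-denominator) moments; kurtosis non-excess (Gaussian = 3); skewness
   and kurtosis are 0 for zero-variance data, judged relative to the data's
   mean square so constant blocks are degenerate despite rounding; entropy
   is a 256-bin equal-width histogram in bits with the bin range taken from
   the whole topomap's min-max (so blocks of one map share a scale) and
   0·log 0 := 0.  The per-map vectors (length s = B²f) form the columns of
   the question's s x L feature matrix FM; each row of FM is summarised
   across the L maps by (mean, SD, skewness, kurtosis) with the same moment
   conventions, giving a 4s-dimensional question vector independent of L
   (5 120 for B = 16, f = 5).  Naive column concatenation (length sL,
   128 000 at L = 100) is provided only for dimensionality comparison.

5. **Feature selection.**  Each feature is scored by `|AUC - 0.5|`, where
   AUC is the Mann-Whitney ROC area of the feature as a ranker of class 1
   vs class 0 with ties credited 0.5.  The score is 0 for identical class
   distributions, 0.5 for complete separation, direction-agnostic, and
   invariant under strictly monotone transforms.  The top k features (ties
   to the lower index) are kept; default k = 500.  By default the selector
   is fit inside each training fold only (`selection_scope = "per-fold"`),
   which is the leakage-free protocol; a `"global"` whole-dataset variant
   exists for protocol comparison and is knowingly optimistic.

6. **Classification.**  RBF-kernel SVM with features z-scored using
   training-fold statistics.  (C, gamma) are grid-searched over the
   canonical ranges C in 2^-5..2^15 and gamma in 2^-15..2^3 (steps of 2^2)
   with inner 5-fold stratified CV; accuracy ties resolve to the smaller C,
   then the smaller gamma.  Evaluation is stratified 10-fold CV with a
   seeded shuffle, reporting per-fold accuracy (%) and ROC AUC with their
   mean ± SD.  Stratification is not part of the original protocol
   description ("randomly partitioned") but keeps balanced folds on
   balanced data; it is the default here.  A repeated-CV runner re-runs the
   whole CV R times with derived seeds (R x 10 fold accuracies, e.g. 50),
   and two systems are compared on such accuracy samples with a two-sample
   pooled-variance t-test (Welch by flag).  Degenerate zero-variance
   samples are defined explicitly: identical constant samples give t = 0,
   p = 1.

## Synthetic studies

No recording from the target protocol is public, so `eegmem.synthetic`
generates studies with known ground truth.  A study is a continuous
recording of back-to-back question epochs with an exactly balanced,
seed-shuffled label sequence; an event table; and a deterministic
concentric-ring electrode layout in the unit head disc.

* **Background** is 1/f^alpha noise (default alpha = 1, SD 5 µV per
  channel), spectrally shaped in the Fourier domain with the DC component
  zeroed.
* **The class-1 effect** is a smooth spatial pattern — a raised-cosine
  taper over the `effect_channel_fraction` (default 0.25) of channels
  nearest a fixed parieto-central focal point — driven by a 6 Hz sinusoidal
  carrier under a slow half-sine envelope spanning the epoch, with peak
  amplitude `effect_amplitude` (default 50 µV = 10x the noise SD).  The
  theta-band carrier is essential: a purely static pattern has its energy
  at the epoch-envelope frequency (~0.25 Hz for 2-s epochs) and is removed
  by the mandated 1 Hz high-pass, which in early testing capped end-to-end
  accuracy near 65% even at 10x noise amplitude.  With the carrier the
  effect lies inside the analysis band and is expressed mainly through the
  SD features and the across-map dispersion of the mean features.
* **Artifacts** (optional, default off): Gaussian-shaped ~100 µV transients
  at Poisson times on the frontal quarter of channels, emulating blinks.

All randomness derives from one root seed through named spawned streams;
regeneration is bit-for-bit reproducible.

What passing the synthetic tests shows — and does not.  The generator
exercises every pipeline contract (shapes, masks, determinism, leakage
protection) and shows the method recovers a strong in-band spatial effect
and stays at chance under the null.  It does not emulate volume conduction
from realistic sources, ERP component structure, inter-subject variability,
or genuine cognitive differences, so synthetic accuracies say nothing about
accuracy on recorded EEG.

## Problem sizes used in the shipped tests

Desk-scale defaults keep the full pipeline fast enough to run routinely:
32 channels, 2-s epochs, 100 questions per class (the balanced-200-question
evaluation design), rendering at 32 x 32 for the end-to-end tests, L = 50
selected maps, 8 x 8 blocks with mean + SD features (s = 128, question
vectors of 512), k = 256 selected features.  A `paper_scale()` preset
(93 channels, 30-s epochs) exists for stress tests.  The end-to-end
acceptance sweep runs the pipeline at effect amplitudes {0, 2, 10} x noise
SD with a fixed seed and checks chance-level behaviour at 0, >= 95% mean CV
accuracy at 10x, and monotonicity across the sweep.

## Numerical and design notes

* Zero-variance detection uses a relative floor (`m2 <= mean(x²)·1e-26`),
  not exact equality, so floating cancellation cannot produce spurious
  skewness/kurtosis of ±1 on constant data.
* The selection tie rule (earlier pair first) and the feature-selection tie
  rule (lower index first) make every ranking deterministic.
* `GridSearchCV` enumerates C ascending then gamma ascending, so its
  first-best tie behaviour implements the documented (smaller C, smaller
  gamma) rule.
* Sample intervals are half-open `[start, end)` and 0-based throughout.
* Known limitations: no ocular-artifact regression (the band-pass plus
  synthetic data make it unnecessary here); linear interpolation only (a
  spline interpolant could be plugged in, but would break the tested
  linearity property); binary labels only.
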