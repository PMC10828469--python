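# Methods

## The problem and the model

Histological signs of aging (lesion burden, tissue disorganization) are
ordinarily graded by pathologists, which is slow and noisy between raters.
This package implements an *electronic Geropathology Score* (eGPS): a
pixel-level age score learned **weakly supervised** — the only label ever
used in training is the slide-level chronological age.

Age is modelled as an **ordinal chain**. For an ordered schedule of K age
groups (default 8, 16, 20, 32 months), a sample's label is a (K−1)-bit
vector whose bit *i* is 1 iff the sample is older than the *i*-th schedule
age: 8 mo → (0,0,0), 16 mo → (1,0,0), 20 mo → (1,1,0), 32 mo → (1,1,1).
The ones always form a prefix, so each channel asks the cumulative
question "is this tissue older than age *i*?" rather than forcing the
model to discriminate adjacent categories outright. (The alternative
"less-than-or-equal" reading of the encoding would give 20 mo the all-ones
vector and break the prefix structure; we use strict greater-than, which
is the convention the printed labels above fix.) The pixel-level training
target — the *ordinal mask* — broadcasts this label over the tissue mask:
channel *i* equals the tissue mask where bit *i* is set, zero elsewhere.

A fully convolutional encoder–decoder (LinkNet-style, see below) maps a
normalized RGB tile to a (K−1)-channel sigmoid probability mask at input
resolution and is trained with per-pixel binary cross-entropy against the
ordinal mask. Background pixels participate with all-zero targets by
default (`loss_on_background=True`); a tissue-only loss exists because
either reading is defensible.

Scoring converts probabilities to a common scale by **rank-based inverse
normal transformation** (van der Waerden scores): within each channel, a
value with average-tie rank *r* among *n* reference values maps to
Φ⁻¹(r/(n+1)). The pixel eGPS is the mean of the K−1 normalized channels;
the slide eGPS is the mean over the slide's tissue pixels.

### Why the reference population is the cohort

The rank-normalization population is a genuinely open design point. If
each slide is ranked against itself, its scores become a permutation of
the fixed quantiles Φ⁻¹(1/(n+1)) … Φ⁻¹(n/(n+1)), whose mean is ≈ 0 for
every slide — slide-level contrast is destroyed by construction (this is
asserted as a regression test). We therefore fit a per-channel empirical
reference distribution on the pooled tissue pixels of a reference cohort
(normally the training cohort) and apply it to every slide. The reference
is stored inside the model checkpoint, which is also what makes it
possible to score a single new slide without retraining or refitting.
Out-of-reference values are clipped to the finite extreme quantiles
Φ⁻¹(1/(m+1)) and Φ⁻¹(m/(m+1)) rather than extrapolated; the empirical CDF
uses the mid-point convention for ties, so applying a reference to its own
sample reproduces the plain rank transform exactly.

## Network architecture

The network follows the canonical LinkNet layout over ResNet-18-style
basic blocks, with every width proportional to `base_width` (w):

* stem: 7×7 conv stride 2 → BN → ReLU → 3×3 max-pool stride 2 (H/4);
* encoder: four stages of two residual basic blocks at widths w, 2w, 4w,
  8w; stages 2–4 halve resolution (deepest stage at H/32, hence the
  requirement that input sides be multiples of 32);
* decoder: four blocks, each 1×1 conv to width/4 → 3×3 transposed conv →
  1×1 conv to the next-shallower width. Decoders 4–3–2 upsample ×2 and are
  added element-wise to encoder stages 3–2–1 (the "link" skips);
  decoder 1 keeps stride 1. Giving all four decoders stride 2 plus the
  two stride-2 transposed convolutions in the head would emit an output
  at twice the input resolution, so the stride-1 decoder 1 is what makes
  the output resolution equal the input — this matches the reference
  LinkNet implementations;
* head: 3×3 transposed conv stride 2 to w/2 → 3×3 conv → 2×2 transposed
  conv stride 2 to K−1 channels.

The probability head is **per-channel sigmoid** by default. A softmax
across channels would force the channels to sum to one, which is
incompatible with multi-hot chain targets such as (1,1,0); softmax is
retained as a configuration option for comparison experiments.

The layers (convolution, transposed convolution via im2col/col2im and
GEMM, batch normalization, max-pooling) and the Adadelta optimizer are
implemented directly on NumPy with explicit forward/backward passes; the
backward pass is verified against central finite differences in float64
as part of the test suite. Single-threaded execution is bit-deterministic,
which is what the pipeline's reproducibility guarantee rests on.

## Training

* Optimizer: Adadelta (ρ = 0.9, ε = 1e−6, overall scale 1.0), the
  batch-default recipe being 60 epochs at batch size 20.
* Hold-out: split **by slide** (never by tile) and stratified by age
  group, fraction 0.2 by default; the held-out loss is recorded every
  epoch and never contributes gradients. The ≥ 2-slides-per-group
  precondition is enforced only when the fraction is positive — a
  fraction-0 split cannot leak and small demonstration runs are legal.
* A zero learning-rate scale is treated as a strict no-op: parameters are
  untouched and batch-norm running statistics are frozen, so the held-out
  loss history is exactly flat.
* Convergence is summarized as the mean held-out loss after a burn-in
  epoch (`convergence_summary`), the usual read-out once the curve has
  flattened.

**Desk-scale preset.** The full-scale recipe processes 300 tiles of
512×512 at batch 20 for 60 epochs, i.e. 15 updates per epoch and ~900
updates in total. The scaled-down configuration used throughout the tests
and the acceptance script — 4 age groups × 5 slides × 6 tiles of 128×128,
`base_width` 8, 20 epochs — uses batch size 6 (16 updates per epoch,
matching the full recipe's update density) and an Adadelta scale of 4.
The scale compensates for the 3× shorter schedule: cold-start Adadelta
steps are near √ε per parameter regardless of gradient magnitude, and at
~320 updates the unit scale does not reliably leave the base-rate plateau
(the solution that predicts each channel's marginal positive rate
everywhere), whereas scale 4 escapes it across initializations. The
full-scale default remains scale 1.0. These problem sizes are the
package's test-scale choice; any of them can be raised in configuration.

## Preprocessing

* Block-mean downsampling by an integer factor (default 20, i.e. a 40×
  scan becomes ≈ 2× context) is applied to the whole image *before*
  tiling; block means commute with factor-aligned tiling (tested), so the
  order is a convention, not a modelling choice.
* Tiles are cut on a non-overlapping row-major grid of half-open
  intervals, partial edge tiles dropped; afterwards every
  `keep_every`-th tile (default 20) of the enumeration is retained as the
  training subset.
* Tissue is detected by luminance thresholding (channel mean < 220 of
  255): stained tissue is far darker than the near-white slide
  background. This replaces interactive outlining and is validated
  against the synthetic generator's ground-truth masks (Jaccard ≥ 0.95).
* The tissue-coverage filter keeps tiles with ≥ 90 % tissue (inclusive
  boundary), applied to training tiles; scoring uses every tile with any
  tissue.
* Channel normalization z-scores each of R, G, B over all pixels of the
  normalization unit. The unit is the whole slide (all its tiles pooled)
  by default — "the mean of all pixels in that channel" — with per-tile
  normalization available as a config switch. The population (n) standard
  deviation is used; at image scale the n vs n−1 distinction is
  negligible, and the choice is switchable (`std_ddof`). A constant
  channel is mapped to zeros with a logged warning. Intensities stay real
  internally and are quantized to 8 bits (round-half-to-even) only on
  export.

## Synthetic cohorts

The generator emulates exactly the structure the method consumes, not
kidney morphology: an irregular tissue blob (thresholded smoothed
Gaussian field) in eosin pink on a near-white background, scattered with
darker purple lesion-like disks. Lesion count per tile is Poisson with
expectation `(base_density + group_index × slope) × area / 10⁴`
(defaults 5 and 5 per 10⁴ pixels), positions uniform within tissue —
the simplest controllable monotone age signal. Tissue fraction is drawn
from (0.92, 1.0) so synthetic tiles mimic tiles that have already passed
a 90 % coverage export filter. Noise is i.i.d. Gaussian (σ = 4 intensity
units), far below the ≈ 55-unit tissue/background luminance gap.

Every tile persists its ground truth (true mask, placed-lesion count,
tissue fraction) for oracle tests. All randomness flows from one seed
through named substreams keyed by (group, slide, tile), so generation is
order-independent and byte-reproducible.

What passing on this generator shows: the pipeline can recover a known
monotone density signal from slide-level labels alone, rank scoring
preserves cohort contrast, and intervention-sized effects are detectable
at n = 8 + 8. What it does not show: robustness to stain variation,
scanner artifacts, anatomical heterogeneity (cortex vs medulla), or
batch effects — none of which are simulated.

## Statistics

One-way fixed-effects ANOVA, Tukey(-Kramer) HSD, Pearson correlation,
partial correlation (residual-on-residual after regressing a covariate
out of both variables, typically chronological age in months), and a
Welch two-sample t-test for two-arm interventions where group variances
need not match. Statistics are computed from the textbook sums-of-squares
formulas; p-values come from scipy's F, t and studentized-range
distributions, and the implementations are tested against independent
references (scipy's `f_oneway`/`tukey_hsd`/`ttest_ind`, pingouin's
partial correlation, the closed-form partial-correlation identity) plus a
2,000-rep null simulation of the ANOVA type-I error rate. The Tukey
family property is asserted in its valid form: the adjusted p dominates
the Fisher-LSD p built on the same pooled error term (a two-sample pooled
t using only the pair's variance is *not* a lower bound when a third
group shrinks the mean-square error, so that naive comparison is not
tested).

## Numerical and edge-case conventions

* Probabilities are clipped to [1e−7, 1 − 1e−7] inside the loss.
* Ties in rank normalization use average ranks; all-tied input maps to 0.
* An ANOVA with zero between- and within-group variance reports p = 1
  with a warning; degenerate Welch/correlation inputs are rejected.
* Slides with no tissue pixels cannot be scored and are rejected.
* Grid coordinates are 0-based and row-major; tile intervals half-open.
* Checkpoints are self-describing (parameters, model config, schedule,
  preprocessing config, quantile reference), so scoring new slides needs
  only the checkpoint.

## Known limitations

* Training cost scales directly with tile count and resolution; the
  NumPy implementation is single-core and best suited to the desk-scale
  presets (width-8 model, 128×128 tiles train in a couple of minutes;
  the full-width 512×512 recipe is expressible but slow).
* No data augmentation, pretraining, or alternative backbones.
* Pyramidal WSI formats are out of scope: inputs are plain PNG/TIFF
  images or pre-exported tile directories plus a manifest.
* The synthetic validation cannot speak to pathologist-score concordance;
  only real annotated cohorts could.
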