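# Methods

`biaslens` quantifies whether an image classifier trained on CT-like data
reads the pathology or a shortcut.  The pipeline has five parts: a
synthetic benchmark with planted, class-correlated artifacts; classifier
contracts (including analytic oracles and a small trainable CNN); seven
saliency/attribution methods; exhaustive simple-average ensemble
selection; and an artifact-localization report.  This note records the
models, the defaults and why, the numerical choices, and what the
synthetic experiments do and do not show.

## The synthetic benchmark

Publication-scraped CT corpora carry content that correlates with the
class label but is causally unrelated to disease: annotation letters
burned into the film, colored markings, off-gray hues, a round
reconstruction frame, the scanner bed, and heterogeneous
contrast/aspect ratio.  The generator reproduces that *structure* with
a stylized body/lung geometry:

- dark noisy background; light elliptical body; two darker lung
  ellipses; for class 1 (and never class 0) a bright lesion blob inside
  one lung — so an unbiased classifier always has a learnable signal;
- five plantable artifacts, each drawn independently per image with a
  class-conditional rate and each recording a pixel mask: `letter`
  (1–3 bright glyph-like strokes near a corner), `colored_marking` (a
  saturated red patch in a different corner, so letter and marking
  masks never overlap), `hue_tint` (a global warm/cold cast; its mask
  is the whole frame), `round_frame` (a thin circle around the body),
  `support_structure` (a horizontal bar near the bottom edge);
- a per-image multiplicative contrast factor drawn from 1 ± 0.15,
  then clipping to [0, 1]; optional aspect jitter (off by default).

The default composition is 746 images in train/val/test = 425/118/203
with class-0/class-1 counts (234, 191), (58, 60), (105, 98).  The
default artifact rates — letter (0.05, 0.60), colored_marking
(0.00, 0.25), hue_tint (0.02, 0.10), round_frame (0.50, 0.50),
support_structure (0.30, 0.70) — make the letter and marking strongly
class-1-associated, the frame uninformative and the support mildly
informative.  **These rates are stand-ins**: no quantitative artifact
census of the real corpora exists, so they are configuration, not
claims about any real dataset.  Randomness uses one substream per
image, keyed `(seed, image_index)`, so generation is deterministic and
order-independent.  Images round-trip through 8-bit PNG (max pixel
error 1/255); masks are stored losslessly.

What passing tests on this benchmark show: that each explainer
correctly localizes the pixels a *known* classifier uses.  What they do
not show: anatomical realism, texture statistics of real CT, or that
any particular real model is biased.

## Classifier contracts and oracles

A black-box classifier maps image batches to softmax rows (pure,
order-preserving).  A differentiable classifier additionally exposes
pre-softmax logits, exact input gradients, and named spatial feature
maps with their gradients.  All gradient-based attribution
differentiates the **logit** of the target class (standard practice;
probabilities are used only as perturbation weights in LIME/RISE), and
every heatmap records that choice in its parameter sidecar.

The *region oracle* is the ground-truth instrument: its class-1 logit
is `gain ×` the channel-weighted mean intensity over a fixed region, so
its gradient is constant inside the region and exactly zero outside.
Defaults are channel-mean weights and gain 6, chosen so the logit of a
bright region in a [0, 1] image stays on the responsive part of the
sigmoid: a saturated oracle (probability pinned at 1 for nearly all
perturbations) is unreadable by any perturbation method, which would
test the oracle's calibration rather than the explainer.  The oracle
also exposes one synthetic 14×14 average-pooled layer of the
region-restricted weighted image, whose gradient has the closed form
`gain · |region ∩ cell| / |region|`, making GradCAM verifiable
analytically.

The trainable model is a deliberately small numpy CNN — three
conv(3×3)/ReLU/maxpool blocks, global average pooling, a linear
two-class head — with explicit backprop (im2col convolutions, Adam).
It is *not* a substitute architecture study: architecture comparison is
out of scope; the mechanism (training, checkpointing, explaining) is in
scope.  A `softplus`/mean-pool variant provides an everywhere-smooth
network for derivative-based analyses; the ReLU/max default is
piecewise linear (maxpool argmax ties make single-pixel finite
differences at kinks meaningless, and a zero-bias ReLU network is
positively homogeneous, which would make integrated-gradients
completeness trivially exact at any step count).

Training follows a two-phase schedule: phase 1 fits only the head with
frozen convolutions; phase 2 unfreezes everything, applies real-time
augmentation (horizontal flip, ±10° rotation, ±10% translation and
zoom — the magnitudes are this package's choice), and after every epoch
saves a checkpoint iff validation accuracy **strictly exceeds 80%**.
Desk-scale defaults are 5 + 16 epochs at 32×32 (the corresponding
full-scale schedule in the source setting was 30 frozen epochs followed
by a long checkpointed phase quoted inconsistently as 200 and as 1000
epochs; neither is usable at desk scale, so both are recorded here and
not resolved).  Because epoch-to-epoch validation accuracy oscillates
at this scale, the returned model carries the weights of the best
phase-2 validation epoch; the checkpoint log is unmodified.

Metrics: accuracy at argmax; binary F1 for the positive (COVID-like)
class; AUC as the rank statistic (ties half) — `None` on single-class
splits.

## The seven explainers

**LIME.**  SLIC superpixels (k-means in CIELAB+xy; requested count
`nslic = 15` by default) define the perturbation units.  `n_samples`
(default 1000) on/off patterns are drawn uniformly, plus the all-on
pattern; "off" segments are replaced by the *image mean color* — a
black fill would itself plant a dark artifact on a mostly dark image;
an exponential kernel on the cosine distance to the all-on vector
(width 0.25) weights the samples; ridge regression (penalty 1.0)
of the class probability on the pattern gives per-segment coefficients.
An exhaustive mode (all 2^n patterns) with penalty → 0 reduces to exact
ordinary least squares and is what the oracle tests use.

**Squaregrid.**  The same surrogate fit run over centered square grids
at levels 2^ℓ × 2^ℓ, ℓ ∈ {1,…,5} by default; interior cells are equal
size ⌊H/2^ℓ⌋ × ⌊W/2^ℓ⌋ with residual pixels absorbed at the edges
(regions of interest are assumed central, so offsets belong at the
borders).  Per-level maps are summed pixelwise with no per-level
normalization.  Levels with sub-pixel cells are skipped with a warning.

**RISE.**  `H = 1/(N p1) Σ_i f(I ⊙ M_i) M_i` with N soft masks obtained
by bilinearly upsampling s×s Bernoulli(p1) grids to a canvas one cell
larger than the image and cropping at a uniform random offset within
one cell.  Defaults N = 4000, s = 7, p1 = 0.5.  All mask randomness is
drawn up front so results are invariant to the classifier batch size.
`keep_prob = 1` is allowed as the degenerate no-occlusion limit (every
mask all-ones, heatmap uniformly f(I)).

**GradCAM.**  `α_k = GAP(∂y_c/∂A^k)`; heatmap
`ReLU(Σ_k α_k A^k)`, bilinearly upsampled to image size and divided by
its maximum when positive, giving values on [0, 1].  Defined only for a
single differentiable network; an ensemble's averaged prediction has no
shared convolutional layer, and passing one raises
"GradCAM is not defined for ensembles of models".  The default layer is
the last spatial layer (deepest convolution before the head).

**Vanilla / Smooth gradients.**  Per-pixel channel-max absolute input
gradient of the class logit (magnitude only — the map does not say in
which direction a pixel matters).  Smooth averages that map over
`n_noisy = 25` Gaussian-noised copies (σ = 0.15 in [0, 1] intensity
units); noisy inputs are not re-clipped, and σ = 0 reduces exactly to
vanilla.

**Integrated gradients.**  Midpoint Riemann sum over `steps = 50`
(inside the commonly quoted 20–300 sufficiency range; midpoint rather
than left-endpoint for lower quadrature bias) along the straight path
from a black baseline; attribution = path-averaged gradient ×
(image − baseline), channels summed, signed.  The completeness gap
|Σ attribution − Δlogit| / |Δlogit| is exposed as a diagnostic.

Scale conventions are carried on every heatmap and drive both rendering
(diverging blue/red centered at zero for signed maps; red-min to
blue-max for RISE; single-hue blue for GradCAM's unit maps; grayscale
for magnitudes) and scoring (positive part for signed/unit maps,
absolute value for magnitudes, min-shift for RISE, whose absolute level
has no defined meaning).

## Ensemble search

Predictions of an ensemble are the unweighted mean of member softmax
rows.  All 2^n − 1 nonempty subsets of n candidate models are scored on
cached per-model validation probability tables (purity of `predict`
makes this bit-identical to re-inference); with 14 models that is
16,383 records in seconds.  Selection: maximal validation accuracy,
ties broken by fewest members, remaining ties by lexicographically
smallest member-id tuple.  The third level is this package's addition:
equal-accuracy equal-size ties genuinely occur at this scale, and a
deterministic rule is preferable to a random pick.  Test metrics are
reporting-only and never consulted for selection.

## The enrichment score and the planted-bias experiment

"The model focuses on the artifact" is operationalized as
**enrichment**: the fraction of a heatmap's nonnegative relevance mass
inside an artifact's mask, divided by the mask's area fraction.
Enrichment 1 is indifference; ≫ 1 is disproportionate focus.  It is
threshold-free and does not conflate artifact size with attention
(unlike raw mass or pointing-game hit rates).  This score is this
package's construction, not a published metric of the setting it
emulates.

The flagship experiment (`report.planted_bias_recovery`) renders
positive scans with a planted letter and explains two analytic
classifiers on each: a letter-keyed oracle (pure shortcut reader) and a
lesion-keyed oracle (legitimate reader).  Across five repeats, every
perturbation/path technique assigns the artifact-keyed oracle strong
letter enrichment (≥ 5) exceeding its lesion enrichment, and the
lesion-keyed oracle reverses the inequality — the desk-scale analogue
of distinguishing a shortcut-driven from a pathology-driven model by
heatmaps alone.

Problem sizes: the experiment runs at a 112×112 rendering with RISE at
32,000 masks.  The reason is a noise-floor property of RISE scoring
worth recording: the min-shift its scale convention requires turns the
Monte-Carlo error of the estimator into diffuse positive mass spread
over *every* background pixel.  That floor scales as 1/√N and is
independent of image size (mask geometry scales with the image), so at
the default 4,000 masks letter enrichment plateaus near 3 at any
resolution, while the artifact-vs-lesion *ordering* is already correct
there.  Raising the sampling budget to ~32,000 masks pushes the floor
well below the planted signal; 112×112 keeps that budget inexpensive.
LIME, Squaregrid and IG pass at their defaults.

## Degenerate inputs and tie-breaks

Constant images yield a single SLIC segment, flagged; constant
classifiers yield zero LIME/Squaregrid coefficients and a flat RISE map
equal to the class probability; a heatmap with zero total relevance
scores mass fraction 0 against any mask; empty masks and empty record
lists are rejected; GradCAM divides by the maximum only when positive;
top-decile outlining selects exactly ⌈0.1·H·W⌉ pixels via argsort
(ties broken by pixel order).

## Known limitations

- The benchmark's anatomy is stylized; nothing here validates the
  explainers on real CT texture, and the artifact rates are invented.
- The trainable CNN is desk-scale; conclusions about architecture
  families (which network family is more artifact-prone) are out of
  scope.
- RISE's absolute enrichment depends on its sampling budget through the
  noise floor described above; compare enrichments across techniques
  only at matched budgets.
- Exhaustive ensemble search is exponential and intended for n ≤ ~20.
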