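# Methods

`nodulecam` re-creates, end to end and at desk scale, a common analysis
pattern in ultrasound computer-aided diagnosis: train a residual CNN to
classify nodule images as benign or malignant, localize the evidence with
Grad-CAM, segment the red (high-contribution) zone of the heatmap, and ask
whether the *shape* of that salient zone differs between the classes.
Because clinical image sets of this kind are not redistributable, the
package ships a parametric phantom generator and demonstrates every claim
on synthetic data.

## Synthetic phantoms

Each image holds one hypoechoic nodule on a speckled background. The
boundary is an ellipse modulated by radial harmonics,

    r(θ) = r_ellipse(θ; a, b, rot) · (1 + Σ_k a_k cos(kθ + φ_k)),

with per-class amplitude budgets: benign draws Σ|a_k| ∈ [0, 0.05] over
harmonics k ∈ {2, 3} (near-elliptical, regular outline), malignant draws
Σ|a_k| ∈ [0.15, 0.35] over k ∈ {3..8} (lobulated, irregular outline). The
two ranges are disjoint, so class separation is enforced by construction —
a deliberate property: it makes "the classifier can discriminate" and "the
salient-region shape differs" well-posed claims on data whose ground truth
is known exactly.

Rendering choices, with rationale:

* **Speckle** is a Gaussian random field, smoothed (σ = 1.5 px),
  re-standardized, exponentiated, and applied multiplicatively. The default
  amplitude is σ = 0.25 in log-intensity. Raw envelope speckle is far
  stronger (Rayleigh, σ/μ ≈ 0.52), but classifiers consume *display*
  B-mode images, which are log-compressed; 0.25 matches the milder texture
  of display-domain images. (An early draft used 0.52; that emulates the
  pre-compression domain and buries the boundary signal that real display
  images plainly show — radiologists and CNNs routinely read these
  boundaries.)
* **Placement** follows the ROI-crop convention of clinical datasets: the
  nodule is centered ± 6% jitter and occupies 18–28% of the image side
  (radius), with eccentricity up to 1.5 and random orientation.
* **Contrast**: the interior is darkened by a factor drawn from
  [0.45, 0.75] (markedly hypoechoic), with a ~1 px softened edge so the
  boundary is not an analytic step.
* Default counts are 415 benign / 93 malignant (the ~4.46:1 imbalance
  typical of clinical series); the scaled test profile uses 60/60.

What the generator does **not** emulate: acoustic physics (attenuation,
shadowing, reverberation), probe geometry, surrounding anatomy,
calcifications, multi-nodule images. A green end-to-end test therefore
establishes that the pipeline's machinery works and that its statistics
detect a truly present shape difference — not that the method would reach
the same numbers on clinical images.

## Classifier

A residual CNN trained with focal loss

    FL(p_t) = −α_t (1 − p_t)^γ log(p_t),   α_t = α for malignant, 1−α else,

with the malignant class as the positive class (TP = correctly flagged
malignant — the clinical convention; the recall emphasis only makes sense
that way). Defaults α = 0.25, γ = 2 (the focal-loss literature's
defaults), probability clamp ε = 1e−7.

Backbone variants:

* `resnet18` — 7×7/2 stem (64 ch), 3×3/2 max pool, four stages of two
  basic blocks at widths 64/128/256/512 (each block: two 3×3 conv + batch
  norm + ReLU + shortcut, projecting 1×1 conv when the channel count
  changes); final feature maps 7×7 for 224×224 input; GAP + linear
  2-class head.
* `tiny` / `tiny_hr` — the same topology in miniature (3×3/2 stem at 8 ch,
  one block per stage at 16/32). `tiny_hr` keeps both stages at stride 1 so
  the final feature maps sit at 1/4 input resolution — twice the saliency
  detail for ~2× compute; it is the scaled-profile default because the
  salient-region *shape* analysis benefits directly from CAM resolution.

The network, backpropagation and Adam are implemented in numpy (im2col
convolutions); gradients are verified against finite differences in the
test-suite. Two details matter at desk scale:

* **Batch-norm recalibration.** With only a few hundred optimizer steps,
  momentum-tracked running statistics lag the weights enough to wreck
  inference-mode predictions. After training, one pass over the training
  set resets each batch-norm's running statistics to the average batch
  statistics.
* **Step decay + flip-TTA.** The learning rate drops 3× at 60% and 85% of
  the epoch budget; evaluation averages the softmax over the four axis
  flips (the augmentation group used in training). Both reduce the
  variance of small-sample training.

Training recipe (scaled profile): resize to 112, random horizontal/vertical
flips and ±15° rotations, normalize (mean 0.5, std 0.25), Adam at 3e−3 for
150 epochs, batch 8. The paper-scale profile keeps the canonical recipe
(resnet18, 224 px, lr 1e−4, 10 repeats) and accepts an optional pretrained
checkpoint; nothing in the tests requires pretrained weights. The 112 px
input is deliberate: downsampling averages the (sub-pixel after resize)
speckle while preserving boundary geometry, which is the class signal.

Evaluation: accuracy, recall, precision, F1 from the confusion table
(undefined ratios are reported as NaN with a warning, never silently 0),
ROC/AUC via the rank statistic (ties ½), and the repeated-experiment
protocol: n stratified 70/30 splits (per-class train count =
⌈0.7·n_class⌉ — the rounding that maps 415/93 to 291+66 train / 124+27
test) with per-repeat seeds derived from the master seed by a fixed prime
stride, so any repeat is reproducible in isolation.

The pipeline separates *evaluation* from *deployment*: the reported
metrics come from the held-out repeated splits, while the checkpoint the
explain stage uses is a final model re-fit on the full dataset (the
standard resampling-evaluation / full-fit-deployment protocol). At this
sample size the distinction matters for the saliency analysis: the
full-fit model's Grad-CAM separates the salient-region descriptors orders
of magnitude more strongly than any single 84-image split model. Flip
averaging, useful for probabilities, is deliberately *not* applied to the
saliency maps: symmetrizing the CAM removes the boundary-arc asymmetries
that carry the shape signal (measured, not conjectured).

## Grad-CAM

For the pre-softmax logit y of the target class (the standard choice;
post-softmax gradients entangle both classes) and final conv maps A^k:

    w_k = (1/Z) Σ_ij ∂y/∂A^k_ij,   L = ReLU(Σ_k w_k A^k).

The raw map is bilinearly upsampled, min-max rescaled (all-zero maps stay
zero), and rendered through the classic jet colormap
(`r = clip(1.5 − |4v−3|)`, `g = clip(1.5 − |4v−2|)`,
`b = clip(1.5 − |4v−1|)`; 0 → dark blue, 1 → dark red). The choice is
load-bearing, not cosmetic: jet's red band (hue ≤ 20°) starts at
normalized value (3.5 − 20/60)/4 ≈ 0.79, i.e. the top ~21% of the range.
A naive blue→red ramp whose red band only covers the top ~8% reduces the
extracted "red region" to the CAM's peak cap — a few dozen pixels whose
shape carries no information (this failure mode was measured, and it is
why the exact colormap is part of the method's definition). Because the
map is piecewise linear, the red-capture threshold is analytically
derivable, and the extraction stage's behavior is exactly characterized.
The explanation target defaults to the predicted class; the overlay blends
0.4 heatmap / 0.6 original.

For this architecture (GAP + linear head) Grad-CAM provably equals CAM up
to a positive scale; the test-suite asserts that equality and checks the
backpropagated channel weights against finite differences.

## Red-region extraction and shape descriptors

The rendered heatmap goes to HSV (H in degrees); pixels with hue in
[0, 20°] ∪ [340°, 360°), S ≥ 0.5, V ≥ 0.3 are "red". 8-connected
components under 50 px (at 224²) are discarded as colormap speckle; the
largest remaining component per image is analyzed (both-regions mode is
available; published figures of this analysis type show one region per
nodule). Its outer boundary is traced as a closed chain of pixel centers
(Moore neighbourhood tracing); holes are ignored.

Descriptors (dimensionless; S area, P perimeter, S_ch/P_ch their convex
hull counterparts):

    form parameter        F = 4πS/P²     (1 for an ideal circle)
    area convexity        S/S_ch         (≤ 1; solidity)
    perimeter convexity   P/P_ch         (≥ 1)

Digital conventions matter here — F is quadratic in P:

* S is a pixel count; S_ch is the pixel count of the rasterized convex
  hull, which keeps S ≤ S_ch exact (this is how regionprops defines
  solidity).
* P uses the Vossepoel–Smeulders corner-corrected chain length
  (0.980·N_straight + 1.406·N_diagonal − 0.091·N_corners). The naive
  (1, √2) chain overestimates smooth digital perimeters by ~4–6% (a disc
  of radius 50 measures +3.9%), which would push a digitized circle's F
  down to ~0.93 and a convex region's perimeter convexity to ~1.05; the
  corrected estimator brings both within 2–3% of their ideal values. The
  naive chain remains available (`estimator="chain"`).
* P_ch is measured with the same estimator on the traced boundary of the
  hull image, so the P/P_ch ratio is estimator-consistent: a convex
  digital region yields exactly 1.
* Residual digitization bias is bounded by a documented slack
  δ = 0.1 on the ideal bounds (F ≤ 1 + δ; P/P_ch ≥ 1 − δ at small sizes).

Validation: a digitized amplitude-0.3 five-pointed star reproduces the
continuous-curve line-integral descriptors within 2%; descriptors are
translation-invariant and scale-stable (r vs 2r within 2%); and over the
amplitude sweep 0 → 0.35 (steps of 0.05) F and solidity are non-increasing
and perimeter convexity non-decreasing — boundary complexity is what they
measure.

## Group statistics

Default test: two-sided Mann–Whitney U (the descriptors are bounded and
non-normal) — exact null for combined n ≤ 20 without ties, normal
approximation with tie correction otherwise; Welch's t is available. Two
degenerate conventions: identical-constant groups report p = 1 with a
warning; per-region descriptor failures become NaN rows and are dropped
per comparison, never fatally. No multiple-testing correction is applied
across the three descriptors by default (a Bonferroni option exists, off
by default, matching how such three-descriptor analyses are usually
reported). Violin summaries are Silverman-bandwidth Gaussian KDEs on a
±5-bandwidth grid (trapezoid-integrates to 1 within 1e−3) plus the
five-number summary. Type-I error is calibrated in the test-suite: label
shuffles of a pooled descriptor population reject at 5% within binomial
bounds over 500 replicates.

## Pipeline

Stages (simulate → train → explain → extract → analyze) communicate only
through files under the configured output directory; each writes a
manifest with the SHA-256 hash of the config that produced it, and every
random draw descends from the single master seed, so a run is reproducible
byte-for-byte. The scaled profile (tiny_hr, 60+60 phantoms, 3 repeats)
completes in minutes on one CPU; the paper-scale profile (resnet18,
415/93, 10 repeats) is provided but takes hours.

## What the desk-scale saliency analysis shows — and the sign flip

On the phantoms, all three salient-region descriptors separate the
classes (typically p between 1e-12 and 1e-3 at n = 60+60), but the
*direction* is inverted relative to the full-scale clinical observation:
here the benign salient regions are the less round ones. The mechanism is
visible in the heatmaps: a small randomly-initialized network has no
object-level features, so its evidence for "benign" is the smooth boundary
band itself — an elongated arc (low circularity, higher perimeter
convexity) — while its evidence for "malignant" concentrates in compact
blobs at individual lobules. A deep ImageNet-pretrained backbone attends
the nodule as an object, so its red regions inherit the nodule's outline
and the direction matches the nodule-level geometry. Consequently:
significance of the three descriptor comparisons is the reproducible
desk-scale finding; the direction check (benign rounder) is asserted on
ground-truth nodule masks, where it holds by construction. The
perimeter-convexity comparison is the least powered of the three and can
fail to reach significance on an occasional dataset draw (measured: 2 of
3 held at p < 0.05 on one of three master seeds).

## Known limitations

* The phantom world is geometric, not acoustic; effect sizes measured on
  it do not transfer to clinical data.
* The scaled profile's classifier is trained from random init on 84
  images; its mean AUC (~0.96 over 3 repeats) has run-to-run spread of a
  few points, unlike the near-ceiling numbers reachable with pretrained
  full-size backbones on real data.
* Descriptor p-values depend on the CAM resolution (1/4 input here);
  coarser feature maps blur exactly the boundary detail the descriptors
  quantify.
* The Mann–Whitney exact mode is only used for tie-free small samples;
  with ties it falls back to the corrected normal approximation even at
  small n.
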