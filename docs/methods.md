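# Methods

This note documents the models and procedures implemented in
`fundus_screen`, the parameters that matter, the choices made where the
design was genuinely open, and the limits of what the synthetic test bed
can show.

## Image conventions

Images are 8-bit (`uint8`) rasters, coordinates are `(row, col)` with the
origin at the top-left, and circle membership is closed
(`distance <= radius`). All clinical distances are expressed in disc
diameters (DD), the diameter of the optic disc as found in the image at
hand, which makes the geometry scale-free.

## Preprocessing

**Green channel.** The green channel of an RGB fundus photograph carries
the most structural contrast (red is near-saturated, blue is noisy); all
detectors operate on it, directly or after intensity complement.

**FSM filter.** The fuzzy switching median filter computes, per pixel,
the window median `m` and the noise evidence `d` = maximum absolute
difference to the window neighbours. A fuzzy membership ramps linearly
from 0 at `t1` to 1 at `t2`, and the output is the membership-weighted
blend of the original pixel and the median, rounded half-up. Defaults
`t1 = 10`, `t2 = 30`, window 3×3 — the common choices for two-stage
salt-and-pepper schemes. Consequences tested: locally flat regions
(`d < t1`) pass through bit-exactly, a single salt pixel in a flat field
is restored to the median, and a pixel whose evidence is exactly
`(t1+t2)/2` lands at the midpoint of original and median.

**BPDFHE.** Brightness preserving dynamic fuzzy histogram equalisation in
four steps: (1) a fuzzy histogram — the crisp histogram convolved with a
triangular membership of half-width `fuzz_radius` (default 4 grey
levels); (2) partitioning at the local maxima of a moving-average
smoothed copy (width 5 bins); (3) per-partition equalisation into output
sub-ranges allocated over the full display range, proportional to
`span × log10(count + 1)` by default (`range_rule="span_log_count"`;
plain `span` is available — the allocation rule is exposed because the
published descriptions differ); (4) multiplicative rescaling of the
result so the output mean matches the input mean, rounded half-up and
clipped. The mapping is monotone non-decreasing, constant images are
returned unchanged, and the output mean stays within one grey level of
the input mean on realistic images (hard clipping at 255 can in principle
bias the mean; mid-range fundus content does not reach it).

An optional mask restricts the histogram, the mapping and the brightness
normalisation to given pixels. The screening pipeline passes the circular
field of view (FOV): without this, the black surround — roughly half the
frame — dominates the fuzzy histogram, distorts the partition structure,
and pushes background grey levels across the fixed exudate threshold.

**Complement usage.** The enhancement chain is run twice per image: on
the green channel for disc, macula and exudate work (these structures
carry their natural contrast there) and on the complemented channel for
vessel segmentation (vessels become the thin *bright* network that a
white tophat isolates). A single complemented chain cannot serve both: a
fixed bright-lesion threshold is meaningless on an inverted image where
exudates are the darkest structure. The `screen preprocess` command
nevertheless writes the classical panel sequence (greyscale, green,
complement, filtered, equalised) with a `--no-complement` switch.

## Retinal structures

**Optic disc.** Circle candidates come from a circular Hough transform
over radii 0.03–0.08 of the image width (typical disc size in 45–50° FOV
photographs; both bounds configurable) on a Canny edge map (σ = 2).
Among up to 20 accumulator peaks, candidates whose interior-vs-surround
contrast (interior mean minus the mean of the annulus out to 1.5 r) lies
in the top decile are eligible — the disc is the image's high-contrast
bright circle — and the strongest accumulator among them wins. Ranking
the decile on *contrast* rather than raw interior brightness rejects
off-centre circles that merely overlap the bright disc; with raw means
such a circle can sneak past the decile cut and out-accumulate the true
disc. No edge support, or no peak above a normalised accumulator floor of
0.25, raises a "no disc found" error.

**Vessels.** Grey opening with a disc structuring element (radius 8 px)
estimates the vessel-free background of the complement-enhanced image;
its subtraction (white tophat) leaves the thin bright vessel network,
thresholded by Otsu (a fixed threshold is available) and cleaned of
components under 30 px. Because the tophat is invariant to adding a
constant, so is the Otsu segmentation.

**Vessel removal.** Vessel pixels are replaced by a Gaussian
normalised-convolution estimate computed from non-vessel pixels only
(σ = 3 px). A plain Gaussian of the original image would leak vessel
darkness back into the fill; the mask-aware estimate fills a vessel line
on a constant background exactly to the background value. When the mask
covers the whole frame the plain Gaussian is the only defined answer and
is returned.

**Macula and fovea.** Three locators:

* *Geometric* (default): candidate fovea positions are sampled on a polar
  grid about the disc centre — distances 1.5–2.5 DD (the fovea sits at
  about 2 DD; ±0.5 DD tolerates anatomical variation), angles within ±37°
  of the horizontal, on the temporal side, i.e. towards the image's
  vertical midline in standard views (forceable left/right). The fovea is
  the candidate minimising the mean intensity of a DD/4-radius window
  (the macula is the darkest structure in the wedge; the window radius is
  a package choice), and the macula region is the 1.3 DD-diameter circle
  around it. The pipeline scores candidates on the vessel-removed image
  so that dark vessel segments crossing the wedge cannot masquerade as
  the macula. The wedge is measured about the horizontal line through the
  disc centre, the more literal of the two possible readings. Grid
  resolution (39 angles × 11 distances) bounds the quantisation error at
  roughly 3–5 px for typical disc sizes.
* *Image centre*: for macula-centred views, a circle of given radius at
  the raster centre.
* *Morphological*: the image is enhanced as
  `img + white_tophat − black_tophat`, which deepens dark structures, and
  the mask is the largest 8-connected component of the pixels in the
  lowest decile of the enhanced image's dynamic range. The decile is
  taken over the (0.5–99.5 percentile) *range*, not the distribution —
  a distribution decile collapses to the whole frame whenever a flat
  background holds more than 10 % of the pixels.

**Circular cropping** zeroes everything outside a circle and preserves
the interior bit-exactly; a circle that misses the raster entirely yields
an all-zero image with a warning rather than an error.

## Lesions

Exudates are the pixels *strictly above* the global threshold `T = 135`
on the FOV-masked equalised green channel, minus the optic-disc circle
dilated by 10 % of DD (the disc is the only comparably bright structure
and its rim bleeds) and minus the vessel mask. Thresholding after the
masking steps is the package's reading of the published order, which is
ambiguous. Raising `T` can only shrink the mask. Maculopathy is the
intersection of the exudate mask with the macula circle, present iff
non-empty — so the maculopathy mask is a subset of the exudate mask by
construction, and its area never exceeds the exudate area.

## Features

For each of the two masks: total on-pixel area, and the mean and sample
SD (n−1, zero below two components) of its 8-connected component areas.
"Mean of the on pixels" admits a second reading — the mean *intensity*
under the mask — which is provided as a documented variant
(`on_pixel_intensity_stats`) but not used by default: component-area
statistics scale with lesion number and size, which is the discriminative
signal for maculopathy grading.

## Classification

Binary labels derive from the 10-stage scale: the four "with maculopathy"
stages are positive; everything else — including advanced diabetic eye
disease, where grading maculopathy separately is no longer meaningful —
is negative. The reference set splits 131/469 under this rule.

Evaluation is Monte-Carlo cross-validation: seeded stratified 90/10
train/test splits repeated ten times, metrics averaged over repeats (a
repeat whose fold lacks a class records the undefined ratio as missing,
not zero), confusion counts summed. The published protocol's wording
("split randomly … repeated ten times") describes repeated random splits,
not 10-fold partitioning, and is implemented as such.

Models: 1-nearest-neighbour (Euclidean), SVM with polynomial kernel
(degree 3 — unstated in the source protocol, the usual default), SVM with
RBF kernel (γ = 1/(p·Var), scikit-learn's "scale"), C = 1 for both, and
Gaussian naive Bayes. Features are z-scored with training-fold statistics
before the distance- and margin-based models; the area and SD features
differ by orders of magnitude, and naive Bayes is unaffected either way.

Class imbalance is handled by seeded random duplication of minority rows.
The default target is the majority size (parity); any target — e.g. the
reference protocol's 521 positives against 469 negatives, whose exact
construction from 131 originals is not derivable and is not guessed — can
be requested explicitly.

## Expert-grading statistics

Stages are coded 1–10 in scale order (supported by the reference boxplot
medians: 1, 2 and 1 for the three experts under this coding). SDs are
sample SDs (n−1), matching standard statistics packages. Quartiles follow
the Tukey median-of-halves rule (no rule is stated in the source; hinges
are the most common boxplot convention). The crosstab reports per-expert
column percentages at one decimal and a Pearson χ² of independence with
zero-margin rows/columns dropped (with a warning). One-way ANOVA across
experts is followed by pooled-MSE pairwise t tests with Bonferroni
adjustment capped at 1.0 — the capped 1.000 entries in the reference
comparisons identify Bonferroni as the adjustment used. Consensus
building from several experts (mean-rounded vs majority) is exposed as a
configuration choice and not used by any statistic here.

## Synthetic generator

The generator renders, on a black frame: a circular FOV; a bright
optic-disc plateau with a soft rim; a dark macula pit (Gaussian profile)
at `macula_dist_dd` DD from the disc along `macula_angle_deg`, on the
temporal side; a seeded random-walk vessel tree growing out of the disc
with tapering width; a linear horizontal illumination gradient; spatially
correlated background texture (Gaussian-filtered noise, σ = 10 px,
SD 1.5 grey levels — fundus background varies smoothly, and white noise
would be amplified by equalisation into blotches no real image exhibits);
optional salt-and-pepper noise; and exudate blobs with a solid core and a
Gaussian skirt (σ = 2 px), so behaviour near the global threshold is
testable (`blob_mode="hard"` disables the skirt). Identical specs yield
bit-identical images.

Default intensities (green channel: background 92, disc 200, vessels 60,
macula 45 deep, blobs 195–220, gradient 14 across the frame) were chosen
once so that the generator's contract holds: after the default FSM+BPDFHE
chain, exudate cores map above the T = 135 threshold and background stays
below it, with margin on both sides. Cohorts randomise disc side and
position, disc radius (±10 %), macula angle (±25°) and distance
(1.85–2.15 DD), and blob placement; positives receive 1–3 blobs inside
the macula circle, both classes 0–2 blobs safely outside it.

**Problem sizes.** Multi-image suites run at 320×480 px with ~24 px disc
radius — the pipeline is scale-free through the DD unit, and this size
exercises every stage at realistic structure-to-frame ratios; single-image
examples use 600×900 with a 45 px disc. The standard study conditions are
a 200-image half-positive cohort for screening and classification
(evaluated with 3 seeds × 10 repeats per classifier), 40 images for disc
recovery, 50 for end-to-end label agreement, and 12 clean
macula-at-2.0-DD images for fovea accuracy.

**What passing does and does not show.** The synthetic bed validates the
geometry and contrast logic of the chain: structure localisation from
planted truth, threshold behaviour around T, the subset and monotonicity
invariants, and the evaluation protocol. It does not validate performance
on clinical photographs: there are no haemorrhages, microaneurysms,
drusen or nerve-fibre texture, blobs are circular, vessels do not occlude
the fovea, and illumination varies only linearly. Classifier metrics near
1.0 on the synthetic cohort reflect the planted class construction, not
expected clinical accuracy.

## Numerical choices and degenerate inputs

Rounding is half-up throughout image arithmetic; outputs clip to
[0, 255]. Thresholds are strict (`>`). Tie-breaks: the fovea grid search
and the largest-component selection keep the first optimum in scan
order. Constant images: FSM and BPDFHE return them unchanged; vessel
segmentation of a flat image is empty; the morphological macula mask of a
flat image is the whole frame. Empty masks give the zero feature triple.
Blank images raise "no disc found"; a search wedge wholly outside the
raster raises "macula out of frame".

## Known limitations

* The fixed threshold T = 135 presumes the BPDFHE output distribution;
  on images equalised differently it needs re-tuning.
* The geometric macula locator assumes a roughly standard view; it
  searches only the temporal side and ±37°, and fails (by design) when
  the wedge leaves the frame.
* On eyes with macular exudates the dark-window fovea score is perturbed
  by the lesions themselves (tens of pixels); the macula *region* is
  tolerant to this, but sub-lesion fovea precision on positives is out of
  reach for this scoring rule.
* Component-splitting: a vessel crossing an exudate splits its connected
  component, inflating component counts and deflating mean areas.
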