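# Methods

## Measurement model

An en-face angiogram is an H×W nonnegative intensity grid with a physical
scale (default 3 mm / 245 px ≈ 12.24 µm/px). The origin sits at the center
of the top-left pixel, x runs along columns and y along rows, in mm; a pixel
is an `mm_per_pixel²` square, so areas are pixel counts times that square
and polygons share the same frame. Intensities are normalized to [0, 1] on
read (integer images divide by their dtype maximum, so 8- and 16-bit
encodings of one scene agree to quantization error).

The region of measurement is an annulus of 0.5 mm inner and 1.25 mm outer
radius centered on the FAZ centroid of the *same* plexus — the deep-plexus
FAZ is substantially larger than the superficial one, so each plexus anchors
its own annulus — with the FAZ interior removed. Annulus membership uses
pixel centers and the half-open interval [inner, outer), which keeps
boundary pixels from being counted twice and makes the raster area converge
to π(outer² − inner²) as resolution grows (0.07% error at 245 px, <0.2% at
4× resolution). If no FAZ outline is supplied the region falls back to the
bare annulus with a logged warning, since an unmasked FAZ deflates density
estimates.

## Vessel segmentation

**Vesselness.** Multiscale Frangi-type tubularity from the Gaussian-scale
Hessian with γ-normalized second derivatives (σ² scaling), β = 0.5, and an
adaptive structureness constant c = half the maximum structureness per scale
(hence exactly zero response on constant images). The response is the
per-pixel maximum over scales and the argmax scale is kept — it is the main
feature separating capillaries (peak at σ ≈ 1 px) from large vessels
(σ ≥ 2 px).

**Binarization.** The contrast-normalized image is pre-smoothed (Gaussian,
σ = 0.5 px at native sampling) and compared against its local mean in an
11 px window plus an offset of 0.08. Two refinements make this robust across
the regimes the tests exercise: (i) locally flat neighbourhoods — and their
surroundings, where the window is dominated by a flat plateau — carry no
usable local contrast and are decided by a global Otsu cut instead, which is
what makes noise-free two-level images recover exactly while speckle noise
stays suppressed (a plain zero-offset local mean would mark half the
background foreground under noise); (ii) window and smoothing scale with
`mm_per_pixel`, because they are physical quantities — with a fixed 11 px
window a 490 px sampling of the same scene puts large vessels wider than the
window and their ragged boundaries sprout skeleton spurs, inflating length
estimates by up to 40%. Components under 5 px are removed as speckle.
Defaults were calibrated on noise-free and noisy synthetic scenes before
being frozen; binarization of a noise-free scene is invariant to intensity
rescaling by construction.

**Large-vessel detection (SCP only).** A pixel seeds a large vessel when it
lies ≥ 2 px deep in the binarized plexus (Euclidean distance transform, i.e.
local width ≥ 4 px), peaks at a vesselness scale ≥ 2 px, and exceeds 0.35 of
the scene's maximum tubularity. Isolated seed clusters under 20 px —
typically capillary-junction blobs, which the Frangi blobness term already
penalizes — are discarded, and surviving seeds grow back to the mask edge by
a bounded dilation (disk radius 3) so the full vessel width is recovered
without recruiting attached capillaries. On synthetic scenes this classifies
vessel pixels by width class with ≥ 90% pixelwise accuracy; vessels near the
30 µm lower end of the large class (≈ 2.5 px) are genuinely ambiguous after
rendering and are only partially recovered, which the areal perfusion
density tolerates. The deep plexus has no large-vessel analysis and DCP
input is rejected.

**Skeleton and length.** Masks are thinned (Zhang–Suen) and each free
endpoint is extended along its local chain direction to the mask boundary:
thinning retreats about half the tube width at every open end, which alone
would bias a 100 px bar 5% short. Length is the sum over unique adjacent
skeleton-pixel pairs of 1 (orthogonal) or √2 (diagonal) times the pixel
pitch, with a triangle correction: a diagonal adjacency whose two pixels
share an orthogonal skeleton neighbour duplicates a corner already traversed
and is dropped (uncorrected it overcounts by up to 41%). This chain rule is
exact on axis-aligned and diagonal paths and overestimates oblique paths by
up to ~8%, which is one reason the synthetic capillary mesh is built on a
jittered lattice (below).

## Outcome metrics

Vessel density is in-region skeleton length divided by region area
(mm/mm²). Note that source tables in this literature sometimes label VD "%"
while reporting magnitudes (≈ 15–22) consistent with mm⁻¹; this package
reports mm/mm² and leaves any rescaling to the caller. By default the
skeleton substrate is the full binarized plexus (the VD definition does not
exclude large vessels); a `capillary_only_vd` flag subtracts the detected
large-vessel mask for sensitivity analyses. Perfusion density of large
vessels is 100 × (large-vessel pixels in region) / (region pixels). Box
counting uses box sides in powers of two from 2 px to ⌊min(H, W)/4⌋ px,
anchored at the foreground bounding-box corner; a box counts if it contains
any in-region foreground pixel, and D_box is the OLS slope of log N against
log(1/s). On a 245 px grid this ladder (2…32 px) reproduces 2.0 for a filled
plane and 1.0 for a line to within 0.02, and 1.85 for the level-5 Sierpinski
carpet against the analytic 1.8928 — the power-of-two ladder on a base-3
fractal carries an intrinsic ≈ 0.04 bias that the stated ±0.05 tolerance
absorbs.

## Synthetic angiograms

Scenes emulate the measurement substrate, not OCT physics. Large vessels are
smooth random walks (step 2 px, heading noise 0.10 rad) entering from a
field edge, steered radially off the FAZ, and rendered as constant-width
tubes (30–80 µm by default) by exact point-to-segment distance. Capillaries
are a jittered square lattice (spacing set so skeleton length per area
matches the configured density, default 15 mm/mm² for SCP and 21 for DCP;
jitter 0.1 × spacing; 15% diagonal edges) rendered as tubes of physical
radius 9 µm (a quarter at 13.5 µm), with a 0.72 px rendering floor so
oblique capillaries do not degrade into dim, diagonally-connected Bresenham
chains. The mostly axis/diagonal-aligned mesh is also the geometry for which
the chain-length rule is unbiased. Segments crossing the FAZ (buffered 2 px)
or a large vessel are omitted entirely, so the FAZ interior contains no
vessel pixels and no centerline is hidden under a large vessel. The FAZ is a
wobbled, rotated ellipse whose polygon is rescaled to the target area
exactly (SCP default 0.31 mm², DCP 1.11 mm²). Intensities: background 0.12,
capillaries 0.80, large vessels 1.0, Gaussian blur σ = 0.5 px, additive
Gaussian noise (default sd 0.05); signal-strength metadata maps monotonically
from noise (10 − 30 × sd, clipped to [0, 10]). Scenes are deterministic per
seed, and `skeleton_length_mm` is the analytic length of the generating
centerlines.

What the generator does *not* emulate: OCTA speckle statistics and flow
dependence, projection artifacts, motion artifacts, vessel caliber
variation along a vessel, and real branching topology. Passing tests
therefore establish that the pipeline recovers known geometry under this
noise model, not that it matches any specific device's output distribution.

## Synthetic cohorts

Each participant draws covariates from per-group distributions (age, sex,
ethnicity, diabetes, systolic/diastolic blood pressure, scan signal
strength) with defaults matching a published three-group memory-clinic
cohort (n = 24/37/29). Metrics are control baseline + additive group offset
+ centered linear covariate terms + Gaussian residual. Default baselines,
offsets and residual scales follow the corresponding published adjusted
group means and coefficients (e.g. superficial VD: control 15.66, MCI
−0.72, AD −0.88, residual sd 0.96). The covariate coefficients are not
published anywhere; small plausible values (e.g. −0.03 VD per year of age,
+0.4 per signal-strength unit) were fixed once so adjustment is genuinely
exercised — their exact magnitudes are immaterial to the contracts tested.
Generating coefficients are returned beside the table so estimators can be
scored against truth.

The enrollment generator reproduces a participant-flow scenario: configured
counts of fatigue, poor-quality (both eyes below the signal-strength 7
threshold) and eye-disease exclusions plus clean participants, shuffled.
Exclusion precedence is fixed (fatigue → quality → eye disease) so tallies
are reproducible; the filter excludes on any flag or when every scanned eye
fails quality.

## Statistics

The adjusted model is OLS of a metric on group indicators (control
reference) plus covariates. Adjusted group means are predictions at the
pooled sample-mean covariate vector (categoricals at sample proportions) —
the estimated-marginal-means convention — so β(group) equals the
adjusted-mean difference identically. CIs and two-sided p-values come from
the t distribution of the fit; constant covariates are dropped with a
warning (they alias the intercept), while genuine collinearity raises an
error naming the offending columns. Reported dispersion includes both the
raw within-group SD and the model SE of each adjusted mean, labeled, since
"adjusted SD" is ambiguous in the literature.

AUC uses the rank (Mann–Whitney) formulation with ties counted ½, reported
as-is (an AUC below 0.5 is flagged, never flipped). Sensitivity at fixed
specificity (default 41.5%, exposed as a parameter) is linearly interpolated
between ROC vertices. Paired AUC differences use the DeLong
structural-components covariance with a normal reference; a marker compared
with itself returns p = 1 by convention. Post hoc power is the two-sample
unequal-variance normal approximation Φ(|Δ|/SE − z₁₋α/₂), which equals α/2
at Δ = 0; this reproduces the published calculator-derived 80.5% to within
0.1 points. Bonferroni control splits α over the outcome family (k = 2 for
the primary VD+FD and secondary PD+FAZ families). The analysis eye is chosen
uniformly among eligible eyes, deterministic per (participant, seed) by
hashing the participant id into the stream.

## Problem sizes and tolerances

Default test and acceptance workloads: 20 seeded 245² scenes for
vessel-density recovery (each |VD − truth|/truth ≤ 5%), 1000 null
replicates at n = 200 for the DeLong type-I rate (0.05 ± 0.02), 200
replicates of the default 90-participant cohort for CI coverage of the
planted −0.88 effect (95% ± 5), and 245² rasters for all geometry oracles.
These sizes give stable Monte-Carlo estimates while keeping the full suite
around half a minute on one core.

## Known limitations

- The chain-length rule's oblique bias (+≤8%) is inherent to the pinned
  counting definition; length on strongly curved real vasculature will run
  slightly long relative to analytic arc length.
- The box-counting ladder is grid-anchored without offset averaging, so
  D_box carries a small systematic bias on base-3 self-similar sets.
- Large-vessel detection is calibrated at the native 12.24 µm/px sampling;
  its pixel thresholds (seed depth, dilation radius, seed-cluster size) do
  not yet rescale with resolution the way binarization does.
- The synthetic noise model is additive Gaussian, not OCTA speckle; real
  angiograms will need the binarization offset revisited against manual
  segmentations.
- One analyzed eye per participant; no between-eye correlation modelling.
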