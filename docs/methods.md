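# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `mbfseg`.  Coordinates, units and defaults stated here are
the package's own conventions.

## Coordinate and angle conventions

Images are `(row, col)` arrays with the origin at the top-left pixel
centre; dynamic series are `(time, row, col)`.  Millimetre distances are
component-wise products with `pixel_spacing_mm`.  The angle of a pixel
`p` about an origin `o` is `atan2(o_row − p_row, p_col − o_col)` mapped
to [0°, 360°): 0° points toward increasing column and angles grow
counterclockwise in the displayed (row-down) image.  No imaging standard
fixes this choice; it is asserted by tests so every angle-valued quantity
(insertion angle, sector boundaries, polar bins) is mutually consistent.
Contours are stored as explicit sub-pixel point lists, not masks, so
border distances below the pixel size are meaningful; masks are derived
by polygon rasterization.

## Phantom

The generator emulates a motion-free three-slice rest/stress perfusion
study.  Geometry per slice: a circular LV cavity (radius 10/9/7 px for
base/mid/apex on a 64×64 grid at 2 mm pixels), an annular myocardium
(outer radius 16/14.5/11.5 px), and on base and mid a crescent-shaped RV
pool hugging the epicardium (80° wide, 6 px thick, spanning
counterclockwise from the true insertion angle, so the anterior junction
is geometrically exact).  The apex has no RV by default, matching its
frequent invisibility on apical slices.

Enhancement is a normalized gamma-variate per tissue,
`A·x^α·exp(α(1−x))` with `x = (t−t0)/(αβ)`, which peaks at exactly `A`
at `t0 + αβ`: RV (t0 3 s, peak 6.6 s, amplitude 3), LV (6 s, 10.2 s, 3),
myocardium (10 s, 17.5 s, 1) on a baseline of 1, sampled at 60 frames /
1 s.  Background tissue gets a slow, early, low-amplitude curve
(t0 1 s, amplitude 0.15, peak ~30 s): weakly and diffusely enhancing
tissue is what surrounds the heart in practice, and it is what makes the
per-pixel-normalized baseline image show dark myocardium against
brighter background — the contrast the epicardial edge detector uses.
A strictly non-enhancing noiseless background would normalize to zero
everywhere and remove that contrast, which no real study does.

Maps are piecewise constant before noise: myocardium at the configured
flow (rest 1.0, stress 3.0 ml/g/min), blood pools at 6× myocardial flow,
background at 0.3 with a smooth patchiness field (±0.15) emulating the
noisier, patchier map background produced by quantifying non-myocardial
pixels.  Defects scale selected sectors' myocardial flow by
`1 − fraction`, optionally per condition.  Default noise: series SD 0.1
(SNR 10 against the myocardial enhancement amplitude), map SD 0.125
(SNR 8 against rest flow).  All randomness flows from one seed; the same
config is bit-reproducible.  The series do not model motion, dark-rim
artifacts, partial-volume at the apex, or arterial input sampling.
Passing tests therefore demonstrate correctness of the algorithmic chain
under idealized acquisition, not clinical-grade robustness.

## Landmark detection

The per-pixel temporal SD image is thresholded at five quantile levels
(75th–95th percentile), each level voting with increasing weight.
Pixels above the 90th percentile form candidate blobs (≥ 15 px,
8-connected).  Blobs are classified by the time-to-peak of their mean
curve: the LV is the latest-enhancing blob with solidity ≥ 0.8 (blood
pools are convex; the annular myocardium is not), ties broken by
centrality; any earlier-enhancing blob is the RV.  This realizes the
functional contract of multi-level SD thresholding + voting +
component-analysis separation of enhancement phases with deterministic,
testable steps; time-to-peak ordering replaces a full independent
component analysis.  Absent enhancement (SD ≈ 0) or no convex candidate
aborts with `LVNotFound` — locating the LV is a hard precondition for
everything downstream, so this is the study-level failure mode.

For the insertion angle, RV boundary-pixel angles about the LV centroid
are rotated so their circular mean maps to 180° (RV left of the LV); the
smallest rotated counterclockwise angle is the anterior junction,
reported in the original frame.  Pixels within 0.5° of the minimum are
tie-broken by smallest radius, since the junction touches the LV wall.
The detector is rotation-equivariant and translation-invariant by
construction, and recovers phantom angles with a mean absolute error of
a few degrees (the idealized crescent makes this easier than clinical
data; the residual error is boundary discretization plus erosion of the
detected crescent by the voting threshold).  The same angle is reused on
mid/apex slices with the origin re-centred on each slice's LV.

## Perfusion-image segmentation

**Temporal normalization** maps each pixel's curve to [0, 1] over its own
range (ε = 10⁻⁶ of the global range guards constant pixels), equalizing
hypoperfused and healthy enhancement.  **Baseline image**: contrast
arrival is the first frame whose LV mean exceeds the first-3-frame mean
by 3 SDs; the baseline is the mean of normalized frames before arrival.

**Epicardial edge**: the baseline image is resampled to a polar grid
about the LV (360 angle bins, 0.5 px radial bins, bilinear).  Because the
polar grid oversamples small arcs, Cartesian pixel noise becomes
angularly elongated streaks; a periodic Gaussian smoothing along the
angle axis (σ 8 bins) suppresses them while reinforcing the angularly
coherent myocardial edge.  Canny (σ 2 bins, hysteresis at 30%/70% of the
95th-percentile gradient) produces 8-connected chains.  Chains are
discarded if they lie inside 1.2× the LV radius (cavity edges), if their
radial inter-quartile spread exceeds 6 px (noise streaks), or if their
mean gradient is below 3× the image's median gradient (no real
contrast — this is what makes a pure-noise image report "no edge" even
though the hysteresis thresholds are relative).  Chains are scored by
angular coverage × mean gradient; among chains within 50% of the top
score the innermost wins, because the RV outer wall produces an equally
strong edge a few pixels further out where the RV abuts the myocardium.
Fragments whose median radius agrees with the seed chain (±3 px) are
folded in.  Per-bin radii beyond 3 px of the circular median are treated
as outliers; remaining bins are filled by a periodic trigonometric
least-squares fit (6 harmonics, order reduced proportionally to angular
coverage so extrapolation over wide gaps stays tame, ridge 10⁻⁶).

**Washout image**: frames strictly after the LV peak, mean-centred per
pixel; the leading right-singular vector rendered as an image, sign
aligned with the temporal-mean image.  It concentrates coherent contrast
kinetics and suppresses noise; note the leading mode is dominated by the
LV washout, so its myocardium/background contrast-to-noise beats a
typical washout frame but not necessarily the single best one.

**Active contour**: classic closed snake (120 points) minimizing
α·elasticity + β·bending − w·|∇(G_σ∗I)|² with α 0.05, β 2.0, w 1.0,
σ 2 px, implicit Euler (step 0.5) on the internal terms, explicit edge
force, max 250 iterations or mean displacement < 0.05 px.  No balloon
force.  A self-intersecting step rolls back and stops; collapse below
25% of the initial area raises `DegenerateContour`.

**Region growing** (LV cavity, and propagated seeds): 4-connected, a
pixel joins when |v − region mean| ≤ 3·SD with running statistics; the
SD is floored at max(2% of the frame's dynamic range, a wavelet estimate
of the frame noise) so uniform seeds and single-pixel seeds are
well-defined.  Growth beyond 40% of the image raises `GrowthOverflow`
(leak into background).  The convex hull folds papillary muscles into
the cavity, so taking the hull boundary as the endocardium excludes them
from the myocardium.  **Slice propagation** correlates each pixel curve
in a window (2.5× the previous epicardial radius) against the previous
slice's LV/RV mean curves; the best pixel seeds growth at the basal peak
frame.  Best correlation below 0.7 means the ventricle is not present
(`LVNotFound` aborts; a missing RV is tolerated and processing
continues).

## MBF-map segmentation

The endocardium is re-grown on the map from the prior LV pixels with
threshold max(3 ml/g/min, 0.5 × median prior-LV flow) — relative so the
criterion survives rescaled maps, with an absolute floor because "blood
pool" has a physiologic meaning; a pool under 10 px raises
`EmptyBloodPool`.  The epicardium is re-detected with the same polar
machinery, restricted to ±20% of the prior's radius profile: outside the
band each angle row is clamp-filled with its band-edge value, which
flattens all gradients there without creating artificial band-boundary
edges.  The already-grown pool is filled with the median myocardial-band
flow first, so the overwhelming pool/myocardium gradient cannot capture
the contour across a thin (apical) wall.  The refined radius profile is
clamped to ±25% of the prior (the prior constrains, it does not merely
initialize; the clamp is configurable).  If no banded edge chain covers
60°, the prior is kept with a warning.  Finally, map pixels above the
97.5th percentile of myocardial flow lying on the outer rim are eroded
(1 px only), the automated analogue of manually excluding anomalously
bright epicardial-border pixels (RV blood, fat, coronaries).
Map-only segmentation without a perfusion-image prior is rejected by
contract — the patchy map background makes it unreliable.

## Sectors

Sector boundaries are `insertion + j·360/n` about the slice's LV centre;
sector 1 begins at the insertion angle, counterclockwise by default
(direction configurable — AHA numbering direction depends on slice
orientation conventions).  A pixel exactly on a boundary belongs to the
sector beginning there.  Default 6 sectors per slice → an 18-sector
study model; `n_sectors` is free for other schemes.  Mean MBF is the
plain average over sector pixels; MPR divides stress by rest per sector,
guarded against rest means below 0.05 ml/g/min and empty sectors.
Conservation (labels partition the mask; the pixel-weighted mean of
sector means equals the global myocardial mean) is exact and tested.

## Evaluation metrics

All area statistics derive from one 2×2 pixel confusion table; kappa
uses the full image as background (no bounding-box restriction — with a
dominant background kappa tracks Dice closely, which the tests assert on
phantom masks).  Border metrics resample both contours to ≤ 0.5 px arc
spacing (discretization error well below the 0.01 mm reporting
precision), apply anisotropic pixel spacing, and use exact
nearest-neighbour distances: `rms_nn` is directed automated→reference by
definition (its symmetric counterpart is ASSD), Hausdorff and ASSD are
symmetric.  The Mahalanobis border distance is defined here as the
distance between the two point-cloud centroids under their pooled
covariance (the standard point-set form; the literature leaves the
border variant under-specified), raising `SingularCovariance` on
collinear sets.  ICC(2,1) (two-way random effects, absolute agreement,
single measures) is computed from the ANOVA decomposition and
cross-checked against an independent implementation in the tests;
Pearson and Mann-Whitney go through scipy.

## Problem sizes and determinism

Tests and the acceptance script use 64×64 phantoms, 60-frame series,
10-study noisy batches, 50 landmark phantoms and a 20-study robustness
batch — sizes at which every stage's behaviour (including failure modes)
is exercised in seconds while remaining faithful to the geometry of
clinical short-axis acquisitions.  All randomness is seeded; identical
configuration and seed reproduce byte-identical outputs, including the
sector CSVs.

## Known limitations

- The phantom's idealized circular geometry and motion-free series make
  segmentation scores (Dice ≈ 0.95) higher than what heterogeneous
  clinical data yields; the pipeline's parameter defaults were chosen
  against this phantom and are all overridable via the YAML config.
- The ventricle detector assumes blood pools dominate the temporal-SD
  image; severe breathing motion or coil-shading (not modelled, and
  corrected upstream in real pipelines) would violate this.
- The epicardial "innermost strong chain" rule assumes the first strong
  edge beyond 1.2× the LV radius is epicardial; pericardial effusion or
  bright sub-epicardial fat could defeat it.
- MBF quantification itself (deconvolution, AIF extraction, motion
  correction) is out of scope: maps are inputs.
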