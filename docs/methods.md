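# Methods

This note documents the models, numerical choices, and limitations behind
`cemsim`. Module order follows the pipeline.

## Image model and geometry

All stages operate on 2D nonnegative rasters with isotropic pixel spacing
(default 0.1 mm/px, the approximate pitch of the GE full-field systems that
produce post-processed CEM images; configurable). Coordinates are row-major,
0-based, with half-open bounds; polygon vertices are (x=col, y=row) in
counter-clockwise order. Images are exchanged as 16-bit grayscale PNG
(lossless, preserves the processed-image dynamic range), masks as 8-bit
{0, 255} PNG, annotation tables as CSV with a mask-file column (the smallest
format that still supports patient-level bootstrap grouping). Processed
mammograms use an inverted lookup table — higher values render brighter — so
multiplicative factors above 1.0 brighten calcifications regardless of the
absolute intensity range, and no assumption is made about that range.

Breast segmentation is Otsu thresholding, largest connected component, hole
fill. A uniformly bright frame degenerates to a full-frame mask; an empty
frame is an error. The CLAHE preprocessing stack (channel 1 = CLAHE
low-energy, channel 2 = raw low-energy, channel 3 = CLAHE recombined) uses
an 8×8 tile grid and clip limit 0.01 of the normalized range; these are
conventional CLAHE settings, exposed in the config.

## Site selection

Texture features are computed per fully-in-breast grid cell (200×200 px;
cells under 90% breast coverage are dropped — partially-outside cells would
mix air into the statistics). The five default features — mean intensity,
standard deviation, histogram entropy (64 bins), mean gradient magnitude,
local range — are pragmatic proxies for "denser tissue with greater
structural variety". The exact radiomics feature set used on clinical data
is not public, so the feature list, directions, and weights are replaceable
config entries. Aggregation is by weighted average-rank rather than raw-value
sums because the features are incommensurable; ranking also makes selection
invariant to monotone rescaling of any feature. Ties break by (row, col)
lexicographic order, making the winner independent of cell-list ordering.

## Candidate extraction

The candidate mask is the logical AND of a binarized Frangi vesselness
response and an intensity-threshold mask (mean + 1·std of the cell).
Defaults: Frangi scales σ ∈ {2, 4, 6} px with standard β parameters,
binarized at the 90th within-cell percentile. The scales are chosen to span
the sizes of the structures being sought: candidate calcifications range
from 0.1 to 1.2 mm (1–12 px at 0.1 mm/px), and a vesselness band computed
only at fine scales (σ ≤ 4 px together with σ = 1 px noise ridges dominating
a tighter percentile cut) is systematically narrower than the larger benign
candidates, which then cannot appear as compact regions in the AND mask.
With scales matched to the size range, both morphology branches are
populated. Both parameters remain configurable.

Connected components are 8-connected. Perimeter is measured as the length of
the marching-squares iso-0.5 contour of the padded region, which removes most
of the staircase bias of pixel-edge perimeters (a rasterized disc of radius
5 px measures circularity ≈ 0.95). Circularity 4πA/P² is clipped at 1.0:
for 1–3 px regions the sub-pixel contour underestimates the perimeter and
the raw ratio exceeds 1, which would wrongly exclude them from a criterion
meant to accept *any* shape. Equivalent diameter is 2·spacing·√(A/π) mm.
Morphology ranges are closed intervals: benign circularity [0.5, 1.0] and
diameter [0.3, 1.2] mm with 10–20 calcifications per cluster; malignant
diameter [0.1, 0.5] mm, any circularity, 20–40 per cluster.

## Cluster growth

Sub-cell contrast is operationalized as (max − mean) over each 10×10 px
sub-cell. The target count is drawn uniformly from the class range; the
search window starts at the winning sub-cell and expands by one sub-cell
ring per iteration, adding filtered regions whose centroid falls inside the
window in deterministic (top, left) order. Growth stops exactly at the
target, so the final count never exceeds the class maximum; if the whole
cell yields fewer than the class minimum, the view is reported infeasible
and skipped — on the default fixtures this affects roughly 1 in 12 benign
views and no malignant views. Given a seed, growth is fully deterministic.
Both views of one breast always receive the same lesion class, enforced at
the pipeline level (the per-view cluster models themselves differ).

## Insertion template and automatic mask

Template values are 1 + amplitude·w per calcification, where w is the
region's normalized interior (Euclidean) distance — 1.0 at the morphological
centre, strictly positive everywhere on the support — so every calcification
pixel exceeds 1.0 and the background is exactly 1.0. The default peak excess
0.15 is a plausible mid-contrast choice; the true system-specific contrast
transfer is not public, and only the >1.0 contract matters downstream.
Degradation convolves the excess (template − 1) with a normalized Gaussian
PSF (default σ = 1 px, conserving total excess to ~1e-6 with zero-padding)
and scales it by (1 − scatter_fraction), default 0.2 — stand-ins for
focal-spot/detector blur and scatter-induced contrast loss. Insertion
multiplies only on the support, so non-support pixels are bit-identical and
the operation is exactly invertible by division.

The automatic lesion mask is: convex hull of all calcification pixels →
outward contour smoothing → rasterization → dilation by 5 px (the margin a
radiologist tends to include around calcifications). The smoothing pass is
corner rounding by *outward displacement*: each corner contributes two
points, the vertex displaced along the outward normals of its two incident
edges (offset 2 px, 2 iterations by default). Classic corner cutting was
rejected because it shrinks the polygon; with a fixed outward offset along
vertex bisectors the original vertices can still fall outside the smoothed
contour whenever the cut points sit far along long edges, so containment of
the original hull could not be guaranteed. Per-edge outward displacement is
equivalent to translating every edge outward and chamfering the corners:
the input polygon is provably contained in the output, the enclosed area is
non-decreasing in the iteration count, and repeated chamfering rounds the
corners. Degenerate supports (< 3 pixels or collinear) fall back to a plain
dilation of the support.

## Enhancement

Measurement: e = meanPV(lesion) / meanPV(background ring) on the recombined
image. The rings come from iterative 1-px 8-connected dilations: the first
stop is the first iteration at which the dilated-minus-lesion count reaches
the lesion count (perilesional ring ≈ equal area), the second stop doubles
that (background ring ≈ equal area); counts overshoot their targets by at
most one dilation shell. Lesions touching the frame border, or covering a
third of it, have no well-defined rings. Ratios marginally below 1 (noise)
clamp to the physical floor 1.0; the raw ratio is available separately. The
measurement presumes the rings lie in breast tissue — rings that spill into
the dark off-breast background inflate the ratio and should be excluded
upstream, as the pipeline tests do. In the clinical workflow the fitted
values are further restricted to lesions missed by the baseline detector;
that is a data-preparation step on the value list, not part of the fit.

Distribution fit: a direct Gaussian kernel sum over the measured values,
evaluated on a 121-point uniform grid over [1.00, 1.06], renormalized so the
weights sum to exactly 1. Bandwidth defaults to Silverman's rule; the
all-equal-values degenerate case falls back to 0.002 (one grid scale), which
is why the kernel sum is implemented directly rather than through a
covariance-based KDE that rejects singular data. Sampling is inverse-CDF on
the grid atoms with uniform within-bin jitter of half a grid step, clipped
to [1.00, 1.06]; since the grid itself is confined to that interval no
post-hoc truncation of the distribution is needed. Samplers are routed by
the (class, view) subset key.

Application: a template equal to e inside the mask and 1 elsewhere is
smoothed with a σ = 5.0 px Gaussian (σ interpreted in pixels; exposed in the
config) and multiplied with the recombined image. The smoothed excess is
exactly zero beyond the truncated kernel footprint (4σ), so distant pixels
are bit-identical; the plateau deeper than ~4σ inside the lesion is
multiplied by e to within 1e-4. Smoothing biases re-measurement downward by
approximately (e − 1)·c·σ/R for a lesion of radius R (edge-deficit argument,
c ≈ 2): at σ = 5 the ±0.005 round-trip tolerance is met for lesions of
diameter ≳ 120 px and the bias shrinks monotonically with lesion size, which
the tests assert on three sizes.

## Evaluation protocol

Predictions below score 0.1 are discarded (strict inequality). Within each
(patient, view) scope, surviving predictions and ground truths are matched
one-to-one among pairs with IoU > 0.1 by maximizing total IoU (Hungarian
assignment). An assignment-based matcher was chosen over greedy descending-
IoU because greedy does not maximize total overlap on instances where one
prediction overlaps two ground truths; the brute-force enumeration oracle in
the tests checks exact equality on random instances. A matched prediction is
a correct detection iff its probability for the true class exceeds 0.5;
a tie at exactly 0.5 therefore classifies as malignant, the configurable
convention. Sensitivity divides correct detections by all true ROIs;
precision divides them by all surviving predictions (correct +
non-overlapping + wrongly classified). With no predictions, precision is
undefined and reported as NaN. For ROC analysis every surviving prediction
contributes its malignancy probability, referenced against the matched
ground truth's class or *benign* if unmatched (a spurious malignant call is
the worse error); AUC is the midrank Mann–Whitney statistic, undefined when
only one reference class is present.

Confidence intervals are percentile bootstrap over patients: 2000 resamples
of n patients with replacement, interval (2.5, 97.5). Patients are matched
once and summarized (correct/true/predicted counts and ROC points), so a
patient drawn twice contributes its summary twice rather than having its
ROIs re-matched against their own copies. Resamples on which a metric is
undefined are redrawn so all 2000 draws count. Paired differences between
two setups on the same patients use one shared resample per draw. Nominal
95% coverage is verified by nested Monte Carlo (92–98% over 200 replicates
of Bernoulli patient metrics).

## Synthetic fixtures

The fixture generator emulates just enough of the statistical structure of
CEM pairs for every stage to be exercised: a half-elliptical breast support;
a clustered lumpy background (Poisson-placed clusters of mildly anisotropic
Gaussian blobs, ~0.5 mm characteristic length — the standard surrogate for
parenchymal texture); caliber-varying curvilinear structures built as
max-combined chains of Gaussian stamps whose radius and brightness drift on
a short correlation scale with occasional wider bulges (real ducts and
vessels show this beading, and it is what gives the candidate mask compact
regions at benign scale, not only thin ridges); and white Gaussian noise.
The recombined fixture is smooth and flat (±0.4% large-scale variation) so
measured enhancement anywhere in the interior is 1.000 ± 0.01. All
randomness derives from one seed; equal seeds give bit-identical pairs.

What the fixtures do *not* model: X-ray physics (scatter, beam hardening,
detector DQE), background parenchymal enhancement and recombination
artifacts, compression-dependent texture anisotropy, correlation between a
lesion's low-energy and recombined appearance, and real inter-patient
variation in density. Tests passing on fixtures therefore validate the
pipeline's contracts (determinism, ranges, conservation, invertibility,
protocol arithmetic) — not clinical realism of the simulated lesions.

Toy annotation sets plant ground-truth discs on a non-overlapping grid and
derive predictions by mask jitter (IoU control), drops, label flips, and
spurious additions, logging the exact confusion counts so evaluation metrics
can be compared with hand-computed values.

## Problem sizes and runtime choices

Default fixture frames are 800×640 px (4×3 grid cells, of which typically
4–6 are fully in-breast) — large enough for a 200 px grid and ring-based
measurement, small enough that a full cluster simulation takes well under a
second. The reproduction script uses 50 seeded simulations per class, 200
planted-disc measurements on 420×420 frames, and 10,000 distribution draws;
the whole run completes in a couple of minutes on one CPU.

## Known limitations

* Benign cluster feasibility depends on the texture offering compact bright
  candidates; ~8% of fixture views are infeasible for the benign branch and
  are skipped, mirroring the skip rule used on clinical data.
* The enhancement measurement is biased low by edge smoothing for small
  lesions (see above) and is unreliable when rings leave the breast.
* Grid cells are anchored at the image origin; a lesion-friendly region
  straddling a cell boundary can be missed. A sliding grid was deliberately
  not implemented.
* The radiomics feature set for site ranking is a documented stand-in, not
  the original clinical feature catalogue.
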