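# Methods

This note records the models, parameter choices and numerical conventions
behind `spheroseg`, and what the synthetic benchmark does and does not
demonstrate about real microscope data.

## Imaging model and coordinates

All computations run in physical micrometres. The default voxel geometry
is 0.64 µm in x and y and 5 µm in z — a 20x water objective with 2x
camera binning and a deliberately sparse z-step that trades axial
resolution for plate-scale throughput; a ~12 µm nucleus spans 2–3
z-planes. z index 0 is the shallowest imaged plane (plate bottom), and
the depth of 1-based plane *k* is *k·dz*, a convention shared by the
height and cutoff metrics so the clearing metric is a pure ratio.
Centroids are reported in a right-handed (x, y, z) frame with the origin
at the corner of the uncropped stack and pixel centres at
(i + 0.5)·spacing.

## Nuclear segmentation

The pipeline is `smooth → detect_pnvs → watershed(h₁) → sort →
watershed(h₂) on residual clusters → sort → merge`, with one parameter
set for all cell types.

**Smoothing.** Anisotropy-aware Gaussian, σ = 1.5 µm in xy and 2.0 µm in
z (converted to voxel units per axis). Large enough to erase sub-nuclear
texture — a dim nucleolus stops being an interior local minimum — while
preserving the intensity boundaries between neighbouring nuclei.

**PNV detection.** Edge evidence is the union of two sign tests on the
smoothed stack: per-plane 2D Laplacian > 0 and full 3D Laplacian > 0
(second differences scaled by 1/spacing² per axis). Bright-blob interiors
are Laplacian-negative, their shells positive, so the tests are invariant
to multiplying the stack by any positive constant — the method relies on
intensity *structure*, never absolute brightness. Non-edge voxels are
additionally required to be above background (Otsu split of the smoothed
histogram — also a relative criterion), then labeled with
6-connectivity: the topological complement of 26-connected edge sheets,
so a one-voxel seam genuinely separates its two sides. Components
touching the xy border (ambient background) and speckle under 30 voxels
are discarded. Interior edge voxels — seams where nuclei abut, nucleolus
remnants — are deliberately *left out* of the PNV mask at this stage:
they are the shape evidence the watershed needs, and are re-filled once
basins are assigned. The stage is biased toward under-segmentation; a
PNV may hold a cluster of touching nuclei.

**Watershed splitting.** Per PNV, independently: Euclidean distance
transform in µm with per-axis sampling (computing it in voxel units would
let the 5 µm z-step dominate the metric), negated so nucleus centres are
minima, H-minima suppression at depth *h*, flooding from the surviving
minima over the hole-filled PNV (enclosed seam/nucleolus voxels flood
last and are divided between adjacent basins, so outputs are solid). The
H-minima transform is grayscale reconstruction by erosion of
(image + h) under the image; flooding uses the standard first-arrival
priority-flood (scikit-image), which is deterministic and matches an
independent hand-written priority-flood label-for-label on handcrafted
dumbbell grids in the test suite. Greedy flooding order, not a
smallest-label ridge rule, is the tie-break: equally deterministic and
identical to the reference flood.

Defaults *h₁* = 0.8 µm, *h₂* = 0.4 µm. The depths sit well below the
nuclear radius scale (~5.8 µm) but above voxelization noise in the
distance field (~half an xy pixel); they were chosen by measuring
splitting of z-adjacent nucleus pairs on synthetic spheroids, where the
neck deficit between touching ~11.6 µm nuclei at the default packing is
of order 1–2 µm. The secondary pass is the *less aggressive* suppression
(smaller *h*, so more minima survive and clusters split further).

**Sorting rules.** An object is a single nucleus (TNV) when its volume
lies in [⅛×, 8×] the sphere volume of the configured mean diameter
(11.6 µm → [102, 6538] µm³, spanning the ±2.2 µm diameter SD
comfortably), its principal-axis ratio is ≤ 3, and its compactness
(volume over the volume of the inertia-equivalent ellipsoid, semi-axes
√(5λᵢ)) is ≥ 0.2. Principal axes come from the physical-coordinate
covariance with the per-voxel box variance (spacing²/12) added, so a
one-plane-thick object is not scored as degenerate. Below the window is
debris (discarded); everything else is a residual cluster. In the final
sorting pass the axis-ratio limit is relaxed 1.5×: an object inside the
volume window that two watershed passes could not split is more likely a
deformed nucleus than a cluster, and packed nuclei do deform. Residual
clusters that still fail after the secondary pass are dropped.

Channel mean intensities in the output records are measured on the raw,
unsmoothed channels; smoothing is a detection aid only.

## Whole-spheroid volume and gating

The gate thresholds the full-stack histogram (Otsu by default; fixed or
percentile by config), closes with an ellipsoidal element of radii
(5, 5, 5) µm (about one z-plane axially), and keeps the largest
26-connected component if it reaches the volume of a 50 µm-diameter
sphere and stays off the first/last xy row/column. Truncation in z is
*not* an exclusion — tall spheroids routinely extend past the imageable
depth and still yield cutoff values. A contrast guard (mean above / mean
below threshold ≥ 3) keeps signal-free wells from producing a mask at
all: any threshold bisects pure noise at a ratio near 2, a real spheroid
scores an order of magnitude higher.

The whole-spheroid mask is the per-plane union of two strategies
computed on *all* planes (no arbitrary shallow/deep switch depth): the
closed union of segmented nuclei (closing radius 8 µm, the inter-nucleus
scale), and a per-plane outline — 15 px (~9.6 µm, larger than one
nucleus) median filter, Sobel gradient, Otsu threshold, fill, largest
region — that still works where blur merges individual nuclei. Deep-plane
regions must beat a 1.3× interior/exterior contrast ratio, which rejects
hallucinated outlines on empty planes. Edge distance is the
anisotropy-aware EDT of the final mask.

## Quality metrics

*Approximate height* = 2·k·dz for the 1-based plane k of maximum spheroid
slice area; undefined unless some later plane falls below 0.97× the
maximum (otherwise the spheroid midpoint was evidently not imaged —
decay on the near side is irrelevant and is not scanned). *Cutoff*: per
plane, segmented-nuclei area over spheroid slice area, smoothed with a
centred 3-plane moving average; the cutoff is the first plane after the
smoothed maximum strictly below 50% of it, else the first plane after
the area maximum with slice area below 10% of the maximum (flagged as
the fallback rule), else undefined (full stack retained). Planes whose
spheroid area is under 10% of the maximum are excluded from the ratio:
at the pole slivers the denominator mask is built from the very nuclei
in the numerator, pinning the quotient at ~1 and faking a mid-spheroid
collapse; the floor deliberately matches the fallback rule's scale.
*Clearing metric* = cutoff depth / height; values over 1 indicate a
mis-approximated height and are flagged and withheld from aggregation.
Nuclei at centroid depth strictly below the cutoff depth are retained
for downstream analysis.

Boundary semantics, fixed in config and tests: "decrease of 50%" means
strictly below half the maximum; depth bins are bottom < 60 µm ≤ middle
≤ 120 µm < top; "within 12.8 µm of the edge" is inclusive; a
label-channel mean exactly at the threshold counts positive.

## Label thresholding

The per-plate threshold is `control_margin ×` the 1st percentile of the
pooled nucleus mean intensities of designated 100%-labeled control
wells. The margin (default 0.5) exists because labeled nuclei in mixed
spheroids are systematically dimmer than in pure controls: in a 100%
control every nuclear ROI also collects blur/scatter spill-over from
labeled neighbours, a boost that vanishes once labeled cells are diluted
— mixing experiments show exactly this maximum-intensity drop. With the
margin the threshold lands in the gap between the mixed-well labeled and
unlabeled populations whenever the channels separate cleanly. Because
the threshold is a percentile times a constant, the positive fraction is
invariant under multiplicative rescaling of the label channel (with the
threshold re-derived from the rescaled controls); a general monotone
transform does not commute with this policy and is not claimed.

## Evaluation

Matching is one-to-one greedy, globally-closest-pair-first, within a
6 µm radius (about half a nuclear diameter); exact distance ties break
on the lower automated index. Greedy matching is not guaranteed
maximum-cardinality; on random ≤ 12-point instances it agrees with a
brute-force maximum matching in well over 95% of cases (tested), and on
realistic sets — nucleus spacing above the radius — disagreement is
rare. Unmatched automated centroids are FP, unmatched ground truth FN;
0/0 ratios are defined as 0 and flagged.

## Synthetic data: what it emulates, what it does not

Each spheroid is a set of ellipsoidal nuclei (geometric-mean diameter ~
N(11.6, 2.2²) µm, mild per-axis eccentricity, random orientation) placed
by rejection sampling in a sphere with minimum centre separation 0.7×
the mean diameter — close enough that neighbours touch and the watershed
is genuinely exercised. Rendering is a winner-take-all partition: a
voxel claimed by several ellipsoids goes to the nearest one, and
intensity is dimmed (to 20%, over ~1 µm) where the two best claims are
close — the dark envelope/cytoplasm seam between abutting nuclei.
Max-compositing interpenetrating ellipsoids instead would leave touching
nuclei with *no* intensity boundary, a condition under which no
segmentation method could separate them and which real tissue does not
present. Per-nucleus lognormal brightness (CV 0.25), a dim nucleolus
spot, a fixed optics blur (σ 0.8 µm xy / 1.5 µm z), optional
depth-dependent attenuation exp(−a·depth) with depth-growing blur, then
background offset and Gaussian (optionally Poisson) noise. Everything is
reproducible from the seed, and the exact centroids/axes/label flags are
the ground truth.

Deliberately not modelled: a physical PSF, refractive-index mismatch,
spherical aberration, chromatic shifts, nuclear shape pathology, debris
and cell fragments, uneven illumination. Passing the synthetic benchmark
therefore demonstrates the pipeline's geometric and topological
correctness under realistic packing, anisotropy and depth degradation —
not its performance on any particular instrument's artefacts. On real
250-cell spheroid data with expert manual ground truth, methods of this
family operate near F ≈ 0.76 with precision well above recall; the
synthetic benchmark (F ≈ 0.87 at the default difficulty) is accordingly
easier than real data, and is used as a regression property, not a
performance claim.

Default study conditions used by the tests and the acceptance script:
250-nucleus spheroids of radius 50 µm (mild noise, no attenuation) for
segmentation accuracy; attenuation 0.01–0.03 µm⁻¹ for degradation
properties (0.03 halves the signal every ~23 µm, a plausibly uncleared
sample); 500-nucleus spheroids of radius 63 µm, two to four replicate
wells per seeded fraction plus 100%-labeled controls, for the titration.
Sizes were chosen so a full run of every check completes in minutes on
one CPU while keeping the packing density (~0.4) of real aggregates.

## Batch contract

Parallel granularity is the well — one stack per worker bounds memory
and matches how plate-scale screening parallelizes. The per-well
pipeline is purely deterministic (the only randomness in the package is
the synthetic generator's seeded RNG), each well writes only its own
files, and the plate summary is sorted by well id, so outputs are
byte-identical for any worker count or completion order. A failing well
is captured as a `failed` outcome with diagnostics; other wells are
unaffected, and gated-out wells are results, not failures.

## Known limitations

Recall degrades for nucleus pairs stacked along z: at a 5 µm step the
junction between two ~11.6 µm nuclei often falls between planes and
leaves neither an intensity seam nor a distance-transform neck — this is
the dominant false-negative mode and an intrinsic cost of sparse axial
sampling. The deep-plane outline assumes one spheroid per field; multi-
spheroid wells analyze only the largest component. The volume/shape
sorting rules are fixed thresholds, exposed in config rather than
learned. Machine-learned parameter selection, cytoplasmic segmentation
and GPU acceleration are out of scope.
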