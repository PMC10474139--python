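# Methods

`ihcmap` reimplements a computational pipeline that adds immune context to
histological phenotypes of murine colitis: single-marker IHC sections
(CD8b, CD3, CD4) cut serially after an H&E section are registered onto the
H&E frame, DAB-positive connected objects are counted per analysis window,
and the counts are mapped onto deep-learning-style H&E patch classes. This
note records the model, its assumptions, the tunable parameters, what the
synthetic data does and does not emulate, and the numerical choices made
where the design was open.

## Coordinate frames and resolutions

Slides are assumed scanned at 40x (0.17 um/px, "DS1"). The pipeline works
at two derived resolutions:

* **DS2** (area-average downsample by 2) — registration and IHC detection.
* **DS8** (a further exact /4 from DS2) — H&E patch classification.

Each swiss roll is cropped along its annotation polygon onto a white canvas
whose dimensions are rounded up to the next multiple of 4 (padding on the
right/bottom edges only). This guarantees the DS2→DS8 rescale is exact and
that the x4 mapping between DS8 patch coordinates and DS2 detection windows
never accumulates rounding error — the property the whole cross-resolution
join relies on. Coordinates are 0-based `(x, y)` with origin top-left and
half-open windows; polygon rasterization is pixel-center-inside with
boundary ties counted inside.

## Serial-section registration

Sections are registered iteratively: section 2 onto the H&E reference,
section 3 onto the already-registered section 2, and so on, so each
pairwise problem involves anatomically adjacent (5 um apart) sections.
Transforms compose into the reference frame; `SpatialTransform` objects are
invertible (round-trip error well under 0.5 px) and composable.

The registration engine is a pluggable contract. The default,
`RigidMaskEngine`, is intensity-free: it works on tissue masks (not stain
values, because H&E and DAB palettes differ) and estimates a rigid
transform by a coarse-to-fine rotation scan (1° grid at 1/16 scale, 0.1°
grid at 1/8 scale, parabolic sub-step interpolation) scored by
phase-correlation residual, followed by subpixel translation via
phase correlation at 1/4 scale. On rigid warps within ±10° and ±50 px it
recovers planted transforms to <1 px at DS2. A deformable stage is
deliberately not part of the default: the synthetic study conditions use
rigid inter-section warps (amplitude-0 smooth warp by default), and rigid
recovery already meets the QC bar. A low-amplitude sinusoidal warp type is
provided for stress-testing the transform algebra.

Tissue masks are "not near-white" pixels (min channel < 235/255) after
morphological closing (disk radius 3) and removal of components < 64 px.
QC is the Dice overlap of the registered section's mask with the H&E mask;
the pass threshold is 0.80 (a number had to be chosen; registration quality
was originally assessed qualitatively). When a mouse contributes two rolls,
the analysis roll is the one whose *minimum* per-section Dice is highest,
ties to the lower roll index.

## H&E characterization

A 32-px micro-patch classifier labels each DS8 cell Tissue, Submucosa,
Muscle or Background; Tissue and Submucosa are "informative". A 224-px
analysis patch is kept iff at most 65% of its area is non-informative —
strictly more than 65% drops it (the boundary keeps). Kept grid patches act
as landmarks for overlapping extraction: axis-aligned shifts of ±20·k px,
k = 1..10, along each of up/down/left/right — at most 41 patches per
landmark. The alternative 21×21 two-axis grid reading (441 patches) is
available behind `grid2d=True` but off by default, matching the
"(up/down/left/right)" gloss. Overlap patches are themselves subject to the
65% rule, computed with exact per-pixel area weighting since shifted
patches are not cell-aligned. Edge tiles smaller than 224 px are discarded,
not padded.

The disease classifier contract maps a 224-px patch to
(p_involved, p_uninvolved) and embeds it as a 512-vector. Confidences are
averaged at every covered pixel; grid patches are labeled from the averaged
field (mean over the footprint ≥ 0.5 → Involved; the tie goes to Involved,
favoring sensitivity). Averaging exists precisely to de-noise dependence on
which tiling happened to be extracted, so the per-patch label comes from
the field, not the raw single prediction. Binary overlays tint covered
Tissue/Submucosa pixels red (Involved) or green (Uninvolved); Muscle and
Background cells are never tinted.

Involved embeddings are reduced by PCA (32 components by default) and
clustered by seeded k-means into k=4 classes (Inflammatory, Crypt Dropout,
Crypt Dilation, Distorted Glands); Uninvolved into k=3 (Crypts, Lightly
Packed, Rosettes). Class assignment is nearest centroid in PCA space, ties
to the lowest centroid index; the k-means seed is fixed at 0. On synthetic
cohorts clusters are named by majority ground-truth label; on data without
ground truth they keep numeric names. Per-roll proportion vectors (pooled
Uninvolved plus the four involved classes) feed a linear discriminant
analysis that predicts the condition as an internal control; when the
within-class scatter is exactly singular the discriminant is fitted in its
nearest-class-centroid limit.

## IHC detection

Detection is stain physics, not learning: `rgb2hed` optical-density
deconvolution with the standard hematoxylin–eosin–DAB stain matrix isolates
the DAB channel. The channel is mapped to 8-bit gray with a *fixed* gain
(255·3 per unit DAB concentration) rather than per-image rescaling, so
thresholds mean the same thing on every patch; the gray image is multiplied
by a per-marker contrast scale (clipped at 255) and thresholded. Connected
components (8-connectivity by default) outside the per-marker area window
are removed. Hematoxylin crystal artifacts — near-black precipitates that
deconvolve to strong DAB — are excluded by thresholding the color-inverted
patch: a pixel is artifact when every inverted channel ≥ 225 (original
near-black in all channels), and any object sharing a pixel with the
artifact mask is excluded (any-pixel overlap, the conservative reading).
Clumped cells are deliberately counted as one object; instance segmentation
is out of scope.

Per-marker parameters (contrast 1.5, DAB threshold 120, area window
[30, 1500] px² at DS2, artifact threshold 225) must be optimized per marker
on real stains; the defaults here are calibrated to the synthetic renderer
and are exposed in config.

Detection is guided by H&E: each kept DS8 patch at (x, y) maps to the DS2
window [4x, 4x+896) × [4y, 4y+896) of the registered IHC canvas. Windows
overlapping a lymphoid-aggregate polygon by >10% are excluded from
statistics (aggregates are constitutively marker-high); windows ≥50% inside
the canvas are clipped with a warning, others skipped.

## Immune-context mapping and statistics

Counts join to patch labels by the x4 law (inner join; orphans are an
error). Within each mouse and marker, the mean count over Uninvolved
patches anchors normalization: involved counts divide by it, so values
above 1.0 mean enrichment relative to the same colon's healthy-looking
regions. A zero Uninvolved mean makes the mouse–marker cell undefined; such
rows are dropped with a logged count. Involved classes below 10% frequency
of a condition's involved patches (computed per condition over the entire
dataset, on unique patches) receive weight 0 and are excluded from
cross-condition statistics; exactly 10% keeps weight 1.

Comparisons: Welch's t-test between Uninvolved and Involved counts per
condition and marker (the pooled-variance form is a config flag); one-way
ANOVA of normalized counts across conditions per (class, marker) restricted
to weight-1 cells; pairwise t-tests of raw Uninvolved counts across
conditions; and an enrichment call at mean normalized count > 1.0. No
multiple-testing correction is applied by default, mirroring how such
figure-level significance is usually reported; zero-variance degenerate
groups take their exact limits (identical groups: t=0, p=1). Patch-level
pooling across mice within a condition is the default for these tests; a
per-mouse-mean analysis can be built from the stacked table.

## Synthetic study conditions

The generator renders fully ground-truthed stacks. Zones are flat-colored
with small, exactly decodable offsets per tissue category and histology
class, so the classifier contracts are satisfied by color decoders without
trained weights; DAB blobs are disks of the canonical brown (DAB
concentration 0.25 under the standard stain matrix), artifacts near-black
4-px specks, and the IHC counterstain a pale lavender. Blobs are placed by
rejection sampling with minimum center separation 2×max radius and an
8+r px margin inside their zone, making counts unambiguous; radii 4–9 px
give areas ~50–254 px², inside the default size window. IHC sections are
rendered in the reference frame and resampled through the inverse of their
cumulative transform with nearest-neighbor interpolation, so color codes
survive exactly and the manifest's transforms reproduce section masks with
Dice ≥ 0.99.

The default cohort is 2 mice per condition (Control, a Klf5-knockout-like
genetic colitis, a DSS-like chemical colitis) with 12 class zones per roll,
each zone exactly one 224-px DS8 patch, over a submucosa strip and muscle
band inside a one-patch white margin (5376² px at DS2). Inter-section
warps are rigid, ±4° and ±20 px per step. Zone classes follow per-condition
mixes (Control mostly uninvolved with rare Inflammatory/Distorted Glands;
Klf5-like enriched in Inflammatory and Crypt Dilation; DSS-like in Crypt
Dropout and Crypt Dilation); every second mouse carries one extra zone of
its condition's dominant involved class, a mild severity gradient that
gives conditions nonzero within-class scatter. Blob counts are Poisson
with per-zone rates = 8 × a condition/class/marker multiplier; the default
multipliers plant the directional findings the pipeline is meant to
recover — CD8b enriched in Klf5-like Crypt Dilation (×1.75 vs ×0.75
uninvolved), depleted in DSS-like Crypt Dilation/Dropout (×0.5 vs ×1.5
uninvolved), and a DSS-like Uninvolved CD8b excess; CD3/CD4 multipliers
follow the same study's involved-region directions.

What the synthetic data does **not** emulate: real histology texture,
nucleus-level morphology, stain batch variability, non-rigid tissue
deformation between sections, clumped or overlapping positive cells,
partial-volume effects at 5 um spacing, and imperfect upstream classifiers.
Passing tests therefore demonstrate that the pipeline's geometry, counting,
normalization and statistics are correct and recover planted effects —
not that the default detection thresholds or classifier contracts transfer
to real slides, where per-marker optimization and trained models are
required.

## Numerical choices and degenerate inputs

* Downsampling is exact integer block averaging (area-average); rounding is
  `rint` (half-to-even).
* The 0.5 confidence tie labels Involved; the 0.65 informativeness boundary
  keeps; the 0.10 frequency boundary keeps weight 1; the 1.0 normalized
  boundary is *not* an enrichment (strictly greater is).
* k-means ties and nearest-centroid ties break to the lowest index; roll
  selection ties break to roll 1.
* Empty tissue masks abort registration with "nothing to register"; a
  failed chain reports its completed sections. Zero kept patches, zero
  Uninvolved patches and sub-minimum statistical groups raise rather than
  silently producing empty outputs.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; equal seeds give byte-identical images,
  manifests and output tables.

## Problem sizes

Default analyses use the sizes above: 5376² DS2 canvases, 12 analysis
patches per roll, ≤41 overlap patches per landmark, 896² DS2 detection
windows, 1000-patch detection calibration batteries, and a 2048² 4-section
stack for registration recovery. These sizes were chosen so a full cohort
study runs in minutes on a single CPU while every zone still spans a full
analysis patch.

## Known limitations

Counts treat clumped cells as single objects; detection thresholds are
stringent by design and undercount weak staining; the rigid default engine
will underperform on strongly deformed real sections (plug in a deformable
engine via the contract for that); the LDA internal control is a
train-set consistency check, not cross-validated generalization; and the
10% frequency weighting is binary, not a continuous patch-frequency
normalization.
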