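# Methods

## The data model and its invariants

A segmentation dataset binds an RGB (or multiplexed) raster, a multi-channel
instance bitmask, and per-type feature tables. The invariants enforced by
`validate_dataset` are exactly those of the representation: integer pixels
≥ 0 with 0 as background; one observation type per channel with unique,
non-empty names and a shared raster grid; table IDs unique, 1-indexed and
positive (but deliberately *not* required to be sequential or gapless); and
row–pixel correspondence — every non-zero pixel value in a channel that has
a table must appear among that table's IDs. Joins between pixels and rows
are always by ID value; a row-position join would silently corrupt any
dataset with gapped IDs, so it is not offered.

Orphan table rows (an ID with no surviving pixel) are flagged only in strict
mode: cropping a slide legitimately removes instances whose feature rows
remain. The validator accumulates every violation rather than failing fast,
because its output is meant to be a machine-readable conformance report, not
an exception. Connectivity is not checked — an instance may consist of
disconnected pixel groups and is treated as one observation throughout.

Pixel coordinates are 0-based (row, col) with the origin at the top-left
pixel, matching the raster conventions of the imaging formats used.

## Storage

Two containers are supported behind one API. The OME-TIFF writer emits one
plane per channel with the channel names in the OME-XML `Channel/@Name`
fields and the sample format chosen as the smallest unsigned integer type
holding the largest instance ID (8/16/32 bit). The chunked store is an
NGFF-flavoured zarr layout — `labels/0` for the label stack with
`channel_names` and `multiscales` metadata, `image/0` for the base raster,
and one AnnData zarr group per table (numeric columns in `X`, categorical
columns in `obs`, original column order preserved in `uns`). Where a
multiscale pyramid is present only the first-listed (highest-resolution)
level is read; pyramid generation is out of scope at desk scale. The
`channel_names` key on the labels group is this package's documented
convention extension; a store lacking it fails with `FORMAT_ERROR` in
strict mode and receives synthetic names plus a warning otherwise.

CSV tables need a linking structure of their own; the manifest is a JSON
list of `{"table", "observation_type"}` objects with at most one entry per
type, relative URIs resolved against the manifest's directory. CSVs use
comma separation, UTF-8, a mandatory header, and an integer `id` column;
numeric columns parse to float64 and anything else is kept as categorical
text (needed for class labels such as globally- vs non-globally-sclerotic
glomeruli).

## Stroked rendering

The stroked rule is implemented exactly as eight lookups at offset
`strokeWidth` in the compass directions; a non-background pixel is stroked
iff at least one lookup differs from its own value. Two boundary conventions
are deliberate: background pixels are never stroked, so outlines are drawn
on instance-interior pixels and never widen the instance; and out-of-bounds
lookups read background, so instances touching the image border are
outlined there (clamping would leave those edges bare). Adjacent instances
with different IDs mutually stroke their shared boundary, the literal
consequence of "differs". Because only eight discrete directions are
sampled, the rule is an approximation: the centre of a small compact
instance can see its own value at all eight offsets and stay un-stroked
(e.g. the centre pixel of a 3×3 square at width 1), and thin diagonal
features may under-stroke. The vectorised implementation is property-tested
against an independent per-pixel loop reference; no monotonicity in
`strokeWidth` is claimed, since none follows from the rule.

Color modes: `static` paints all non-background pixels of the channel one
RGB; `set` routes instance → set → RGB and leaves unmapped instances
transparent; `feature` min–max normalises the channel's feature vector,
rescales through the `[colormapRangeStart, colormapRangeEnd]` window with
clamping, and maps through viridis or magma. The window formula is the
common slider semantics; a constant feature vector normalises to 0.5 by
convention (the midpoint is the only value that treats no instance as an
extreme). Per-pixel alpha is `round(opacity × 255)`, multiplied by the
layer opacity at compositing time. Compositing is straight-alpha "over" in
float64, quantised once at the end; the output tile is fully opaque.
Viewport renders compute stroked masks on the full plane before cropping,
so a zoomed tile equals the corresponding crop of a full-frame render.

## Pathomic features

The four classic feature classes are covered by a minimal, exactly testable
set (the full clinical feature batteries live in dedicated pipelines and
are not reproduced): pixel-count area (and µm² area when a pixel size is
known), exterior 4-connectivity boundary count as perimeter, second-moment
ellipse aspect ratio and eccentricity, centroid, per-band RGB mean and
population SD, Euclidean-distance-transform thickness (max and mean; a
pixel adjacent to background has distance 1), and luminal fraction — the
fraction of instance pixels whose unweighted RGB mean exceeds a threshold
(default 200 on the 0–255 scale), a color-thresholding proxy for open
lumen. Texture is represented by the per-band intensity SD; co-occurrence
textures are deferred.

Numerical choices: each instance's distance transform treats everything
outside the instance — including other instances and the image border — as
background; a single-pixel instance has aspect ratio 1 by convention while
a one-pixel-wide line has aspect ratio ∞ (zero minor axis); disconnected
pixels sharing an ID contribute to one row. `batch_extract` skips channels
with no instances (an empty region channel in cropped data is normal)
while `extract_features` on an empty channel raises `EMPTY_CHANNEL`.
Without an image, only geometry columns are emitted.

## Region stratification

Instance-to-region assignment is binary (inside/outside) with two rules:
`centroid` — the rounded centroid pixel lies on a non-zero region pixel —
and `majority` — strictly more than half the instance's pixels overlap the
region. Centroid is the default: it is cheap, unambiguous, and matches the
intuition of an instance "lying within" a region; majority is provided for
elongated instances straddling boundaries. Only zero/non-zero matters in
the region channel. A three-way split (e.g. cortical IFTA / cortical
non-IFTA / extracortical) is composed from two binary assignments with
`combine_region_labels`; how the enclosing region (total cortex) is
delimited is left to the supplied region channel.

`compare_strata` reports per-stratum n, median and IQR, shared-bin
histogram counts, and a two-sided Wilcoxon rank-sum test with midranks for
ties. With at most 20 observations per group the p-value is exact:
p = P(min(U₁, U₂) ≤ observed min) under the permutation null. For untied
pools this is evaluated with a rank-sum counting recursion (fast and exact
at any allowed size); tied pools are enumerated directly when the number of
assignments is at most 2·10⁵, beyond which the tie-corrected normal
approximation with continuity correction is used — full enumeration of
tied pools near 20-per-group is computationally out of reach, and the
chosen definition makes identical samples give p = 1 exactly. The `method`
field of the result records which branch ran.

## The synthetic generator

The generator emulates the channel structure of segmented cortical kidney
tissue, not its appearance: a pale PAS-pink background (RGB 243, 217, 227)
with σ = 4 Gaussian noise, and per-type constant-colored instances — disks,
second-moment ellipses, or blob unions of jittered disks — placed by
rejection sampling without intra-channel overlap (cross-channel overlap is
allowed, as in real tissue where capillaries sit between tubules). The
default fixture is a 256×256 canvas at 0.5 µm/px with 4 glomerulus disks
(radius 10–16 px), 8 tubule ellipses (semi-major 8–14 px) and 20 PTC disks
(radius 2–4 px) — the size ordering and relative abundance of a
low-magnification cortical field, at a scale where every test runs in
seconds. Region channels are large blob unions sized to a target coverage
fraction. The stratification fixture covers ~25% of the canvas with an
IFTA-like region and draws PTC radii 4–6 px outside vs 2–3.5 px inside it.

Ground truth records each instance's painted pixel count (recounted from
the plane, hence exact), centroid, shape parameters and region placement.
Randomness is a single seed split into one `SeedSequence` child per channel
(image noise first, then regions, then instance types), so extending a spec
never repaints earlier channels. Instance IDs are 1..n by default; an
optional order-preserving gapped remapping exercises the non-sequential-ID
clause. Because instance colors are exact constants and placement is
overlap-free within a channel, color and area recovery are exact — which is
precisely what makes the fixtures good oracles and also what they do *not*
show about real data: stain variability, touching instances of one type,
segmentation noise and texture are all absent, so passing tests demonstrate
correctness of the computations, not robustness to imaging artifacts.

## Problem sizes

Default verification scales are 256×256 canvases (360×360 for the
100-instance feature-recovery run), 200 random planes up to 256×256 for the
stroked-rule cross-check, and 100 seeded replicates for the stratification
recovery rate; all were chosen so the whole suite and the acceptance script
each complete in well under a minute on one CPU while still exercising
multi-instance, border-touching and gapped-ID cases.

## Known limitations

Polygon/shape representations, DICOM, full SpatialData containers with
coordinate transforms, pyramid generation, anti-aliased outlines, Haralick
textures, and sub-compartment thickness features are out of scope. The
renderer samples exactly eight directions per pixel, as specified, with the
under-stroking consequence noted above. Remote object stores are not
supported; all paths are local.
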