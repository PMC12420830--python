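# Methods

`spotcta` implements computational tissue annotation (CTA) for Visium-style
spatial transcriptomics of tumor sections: per-cell tumor/immune/stroma
labels inferred from the paired H&E image, aligned to the 55 µm capture
spots, and used downstream to benchmark expression deconvolution, guide
copy-number clone calling, and gate molecular subtype estimation. This note
records the models, the tunable parameters, the numerical choices, and what
the synthetic fixtures do and do not demonstrate.

## Stain model and optical density

Light absorption by histological dyes is multiplicative in transmittance
and therefore additive in optical density (Beer–Lambert): for channel
*c*, OD_c = log10(I0_c / I_c), with I0 the background white point. A pixel's
OD vector is modeled as a non-negative combination of two unit stain
directions (hematoxylin, eosin) plus residual. `rgb_to_od` floors pixel
values at 1 and clips to [0, `od_max`] (default 2.0), so saturated-black
pixels report the ceiling rather than infinity.

Stain vectors are estimated per image in the standard automated way
(`StainVectorEstimator`): the background is the median of the brightest
pixels (above the 0.95 brightness quantile); pixels with OD norm below 0.10
are treated as unstained; pixels whose OD direction leaves the dominant
2-D plane (SVD of the stained OD cloud) by more than 25 % of their norm are
discarded as unrecognized colors; the hematoxylin and eosin directions are
the 1st/99th percentile extreme angles within the plane, assigned by red-
channel absorption (hematoxylin absorbs red most). On images synthesized by
the forward model the recovered vectors agree with the truth to cosine
similarity ≥ 0.999; on rendered scenes (quantized to 8-bit, blurred,
overlapping dyes) agreement is ≈ 0.999 for eosin and ≈ 0.998 for
hematoxylin.

## Segmentation and features

Nuclei are detected on the hematoxylin channel (OD projected on the
hematoxylin vector): Gaussian smoothing (σ = 1.5 µm), Otsu threshold (an
absolute threshold can be supplied), Euclidean distance transform, peaks at
least 3 µm apart as markers, and marker-controlled watershed. Objects
outside [5, 400] µm² are discarded. All length parameters are micrometers
and are divided by the pixel size; passing `pixel_size_um = 1` gives the
pixel-unit mode for images without physical metadata.

Cells are grown from nuclei by distance-limited competitive dilation
(default 3 µm): contested pixels go to the nearest nucleus, so cell masks
are disjoint and contain their nucleus; cytoplasm = cell − nucleus. Features
per cell: nuclear and cell area (µm²), circularity 4πA/P² capped at 1, and
mean/max hematoxylin-OD and eosin-OD over nucleus, cytoplasm and cell. A
cell with an empty cytoplasm keeps its row with cytoplasm features missing.

Spatially smoothed copies of every feature are appended for radii 25 µm and
50 µm: a Gaussian-distance-weighted mean over neighbors within 2·radius,
weight exp(−d²/2σ²) with σ = radius/2, self-weight 1. The kernel shape is a
package choice (the operation and radii are fixed, the kernel is not
externally specified); a Gaussian is the conventional default.

## Classification

`CellTypeClassifier` z-scores every feature with training-set statistics
(constant features get unit scale and are flagged) and fits a random forest
(100 trees, √p features per split, unlimited depth, seeded). Prediction is
argmax of the forest's class probabilities with alphabetical tie-break.
The iterative annotate-train loop of interactive use maps to repeated `fit`
calls on a growing training table; no interactivity is modeled.

## Spot geometry and composition

When spot coordinates live in a down-sized registration image, the scale
factor is s = registration height / full height, and pipelines that
registered a vertically flipped image additionally need y_full = H_full −
y/s. Both the flip convention and the standard Space Ranger convention
(coordinates already in full-resolution pixels) are supported. H is used as
stated (length convention), not H − 1.

A cell joins a spot when its centroid falls in the square window center ±
radius on both axes, boundaries inclusive. With genuine Visium geometry
(radius < pitch/2) the squares are disjoint; for adversarial grids a cell
in several squares goes to the nearest center, ties to the smallest
barcode. Unassigned cells are reported, never silently dropped. Per-spot
counts and fractions of the three classes form the composition table, the
pipeline's central exchange object.

Spot QC removes spots with fewer than 500 detected genes, more than 25 %
mitochondrial UMIs, or more than 20 % hemoglobin UMIs — all strict
comparisons, all configurable, with per-spot reasons reported. Spot density
of a group is total annotated cells over member spots divided by the number
of member spots.

## Deconvolution scoring

Fine-type fraction matrices (any deconvolution method's output) are summed
to tumor/immune/stroma through an editable fine-type map; the shipped
default groups the 29-type breast tumor taxonomy with both cancer and
normal epithelial counting toward "tumor", matching the morphology classes
the annotation produces (a judgment call: morphology cannot separate the
two). Spearman's ρ (average-rank ties) is computed per section and class
over QC-passing spots with at least one annotated cell; groups below 3
spots are flagged rather than scored. Methods are compared per class with
Kruskal–Wallis over per-section ρ, then Dunn's z-test of each method
against a reference method (normal approximation, tie-corrected pooled
variance), Benjamini–Hochberg within the class, stars at 0.05/0.01/0.001.
Dunn's test is implemented from the rank-sum formula and verified against
the closed form in tests.

## CNV clones

Reference spots are QC-passing spots with zero annotated tumor cells and at
least one annotated cell (spots with no cells at all carry no annotation
evidence and are excluded). Query spots have tumor fraction ≥ τ, τ ∈
{0.5, 0.7, 0.9}, inclusive.

The relative-expression profile is a deliberately compact six-step core —
depth-normalize to 10⁴ and log2(x+1); drop genes with mean normalized
expression ≤ 0.1; subtract the per-gene reference mean; clip at ±3;
101-gene running mean within each chromosome (truncated at ends); center
each spot at its median; zero values within 1.3·SD of zero, where SD is the
spread of the reference spots' own profiles. There is no HMM state calling,
no Bayesian filtering and no subclustering; the simplification is
sufficient for clone separation when segmental gains/losses exist, which is
what the fixtures and tests exercise.

Query profiles are per-gene z-scaled (optional) and clustered with Ward
linkage. Both R-style variants are available: `ward.D` (classical Ward run
on the given Euclidean distances, obtained by feeding √d to scipy's ward
and squaring the heights back) and `ward.D2`; partitions agree with R's
`hclust`/`cutree` on fixtures. The dendrogram is cut at k clusters or at a
height — published cut parameters are ambiguous between the two readings,
so neither is privileged — and clones are lettered A, B, … by decreasing
size.

## Cohort reports

Subtype eligibility: QC pass AND deconvolved epithelial fraction ≥ 0.20 AND
≥ 1 annotated tumor cell. Group composition summaries pool counts
(Σ class counts / Σ totals per group), not means of per-spot fractions —
the pooled reading matches one-stacked-bar-per-cluster displays; the
mean-of-fractions alternative is provided separately. Pseudo-bulk sums raw
counts per group, scales columns to CPM (10⁶) and applies log2(x+1).
Transcript subsampling draws round(f·n) points without replacement per
marker, seeded, to visually match transcript density to annotated cell
counts on image-based platforms.

## Synthetic data: what it emulates and what it does not

The scene generator renders nuclei as blurred filled ellipses with an eosin
cytoplasm halo, mixed through the forward Beer–Lambert model with the
reference stain vectors, over a clean background. Class appearance defaults
(nucleus equivalent radius, eccentricity, stain intensity) are chosen so
that classes differ by several SD in nucleus area and eosin OD — large
round tumor nuclei, small dense lymphocyte-like immune nuclei, elongated
stroma nuclei — which is what makes end-to-end recovery a meaningful
round-trip test of the machinery rather than of histology realism. Not
modeled: staining artifacts, folds, focus gradients, nucleus overlap,
texture. Passing tests therefore demonstrate correctness of the pipeline's
mathematics and bookkeeping, not expected accuracy on real slides.

Centroids are rejection-sampled with a hard minimum spacing and a 10⁵
attempt cap (deterministic failure naming the densest class instead of a
hang). Deconvolution fractions per spot are the true composition perturbed
by Dirichlet noise of concentration c (c = ∞ disables noise), split
uniformly among each class's fine types; the parts are constructed so their
floating-point sum reproduces the class mass bit-exactly, making the
zero-noise ρ = 1 check sharp. Counts are Poisson around a gamma-distributed
baseline scaled to depth 10⁴ per spot, multiplied by 2^log2FC inside
altered segments; a negative-binomial flag adds overdispersion.

## Problem sizes

Defaults used by the tests and the acceptance script: 1300² px scenes with
150 cells; 6×6 spot grids (100 µm pitch, 55 µm spots) with ~400 cells; 600
genes on 4 chromosomes with 100 reference plus 200 query spots and 150-gene
segments at log2FC ±1; 50 noise replicates per concentration and 1000
simulated families for the null calibration. These sizes give stable
statistics while keeping a full run in seconds.

## Known limitations

- No pyramidal whole-slide I/O, no cross-slide color normalization, no
  learned segmentation.
- Geometry supports uniform scale + y-flip only; no nonrigid registration.
- The CNV core is relative expression only: no absolute copy number, no
  allele-specific events, and short chromosomes (< 2 genes) are skipped.
- Dunn's test uses the large-sample normal approximation; very small method
  groups (< 2 sections) are excluded rather than exactly tested.
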