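# Methods

This note documents the models, estimators and numerical choices behind
`ocquant`, and what the synthetic-data studies do and do not demonstrate
about real data.

## LSO soma quantification

**Local normalization.**  Segmentation pre-processing follows the standard
Gaussian local-contrast form: subtract a Gaussian-weighted local mean and
divide by the Gaussian-weighted local standard deviation,
`(I − G_σ₁∗I) / max(√(G_σ₂∗(I − G_σ₁∗I)²), ε)`.  Both sigmas default to
25 px and ε to 10⁻⁶ of the image dynamic range; boundaries use
nearest-value padding.  Normalization feeds segmentation only — all
measurements run on the raw image.

**Segmentation.**  The built-in segmenter (Otsu threshold → hole filling →
distance-transform watershed, watershed seeds ≥ 7 px apart) is a
deliberately simple fallback; any external instance segmentation (e.g. a
deep-learning segmenter) can be supplied as a label TIFF, and the rest of
the pipeline is agnostic to its origin.

**Curation.**  An object survives iff (a) its centroid lies inside the
anatomical boundary polygon, boundary inclusive (shapely `covers`); (b) its
mean raw intensity reaches the threshold in at least one marker channel;
(c) its shape is cell-like: area within 50–2000 px², eccentricity ≤ 0.95,
solidity ≥ 0.8.  All criteria are configurable; removal reasons are logged
per label.  Curation is idempotent by construction.

**Neuropil subtraction.**  Per cell, the background region is the soma mask
dilated by 20 px minus the union of all somata dilated by 5 px.  Dilation
radii are in pixels with a Euclidean disk (implemented as a
distance-transform threshold, which is exact for disk structuring
elements); image borders clip the annulus.  If the annulus is empty, the
median of the channel beyond 20 px of every soma (inside the boundary
polygon when given) substitutes, and the cell is flagged.  `corrected =
soma_mean − neuropil_mean` may be negative at this stage.

**Coordinates.**  Row-major, 0-based pixels; polygon vertices and axis
endpoints in (x, y) image coordinates; centroids projected orthogonally
onto the medial→lateral segment, scaled by its length, clamped to [0, 1].

## Gradient inference

Intensities per LSO are floored at zero and divided by the brightest cell;
the slope of normalized intensity on normalized position is fitted by OLS.
Two 95% intervals are reported:

* `ci_low/ci_high` — the classical OLS slope interval (residual-based
  standard error, t critical value with n−2 df).  This is the quantity most
  readers expect and is appropriate for comparing slopes *between* groups.
* `ci_low_adj/ci_high_adj` — a pipeline interval for comparing the fitted
  slope against an externally known value.  Two extra variance terms are
  propagated:
  1. **Normalizer uncertainty.**  Dividing by the brightest observed cell
     makes the estimate `b ≈ β·M/M̂`; the measurement error of that single
     cell adds slope-proportional variance `b²·s²` (s² = residual
     variance), invisible to the residual-based standard error because it
     rescales all points together.
  2. **Spatial residual correlation.**  Cells close together in the section
     share local background (imperfect neuropil subtraction of any smooth
     background field), so residuals are positively correlated and the iid
     variance is too small.  The slope variance uses a model-based
     Conley-type sandwich: the empirical residual covariogram (mean
     cross-product in 20-px distance bins out to 240 px, clipped at zero)
     is plugged in as the off-diagonal covariance.  When the cell table
     carries no coordinates, a Newey–West estimate over position-ordered
     residuals (bandwidth √n) substitutes.
  The adjusted standard error is floored at the OLS value, so the adjusted
  interval always contains the classical one.

In simulation this interval is calibrated (z-standard-deviation 0.96–1.01)
where the classical interval undercovers badly at steep slopes.

**Expressing fraction.**  The fraction of cells whose *raw* corrected
intensity exceeds a per-protein threshold.  Thresholds are user inputs
(they are calibrated against manual counts in practice);
`threshold_sweep` reports the full fraction-vs-threshold curve to support
that calibration.

**Group statistics.**  The Wilcoxon rank-sum test enumerates exactly when
n₁+n₂ ≤ 12 without ties, otherwise uses the tie-corrected normal
approximation.  `anova_from_summary` computes one-way ANOVA from group
means, SDs and sizes alone; it is algebraically identical to the raw-data
ANOVA for any sample reproducing those summaries (tested against
`scipy.stats.f_oneway` at 10⁻⁹).  The photobleach/depth correction is
multiplicative and order-independent, `raw / (1 + b·n_flashes) /
(1 + d·depth)`, with both slopes (< 0) fitted to calibration series of
relative intensity; factors ≤ 0 are refused rather than extrapolated.

## Cochlear axon analysis

**Place–frequency map.**  `F(kHz) = 10^((a − d)/b)` with a = 156.5,
b = 82.5 and d the percent distance from the cochlear base — the standard
mouse map; both parameters are configurable for other species.  The
closed-form endpoints are 78.88 kHz (base) and 4.84 kHz (apex); the
forward/inverse round trip is exact to < 10⁻⁹ percent.

**Puncta detection.**  The axon-masked synaptophysin channel is smoothed
with a Gaussian at the 0.115 µm surface-grain scale (sub-voxel grains act
as voxel-level smoothing), thresholded at a user-set absolute level, and
labeled with 26-connectivity.  Components whose equivalent spherical
diameter exceeds 1.6 µm are divided by a distance-transform watershed whose
seeds are at least 1.6 µm apart; a smooth blob yielding a single interior
maximum is bisected across its principal axis instead.  The grain size is a
mesh parameter in the original surface-rendering tool with no exact raster
analogue; treating it as a pre-threshold smoothing scale is this package's
interpretation.

**Proximity ≤ 0.**  "Touching or overlapping" between binary surfaces is
rasterized as voxel overlap OR 26-connected adjacency: a punctum is
NPY⁺/On-CALB2 iff any of its voxels falls inside the respective surface
dilated by one 26-connected shell.  This is the raster analogue of
mesh-surface distance ≤ 0.

**Morphometrics.**  All geometry is computed in physical µm (anisotropic
voxels supported).  Branch points are nodes with ≥ 2 children; branch depth
is the maximum number of branch points on any root→terminal path; the
tonotopic span defaults to the frequency extent of the stem, terminals and
puncta combined (configurable to puncta-only or terminals-only, since the
choice is not uniquely determined by convention).  Turn direction compares
the maximum terminal extents toward apex (e_a) and base (e_b) from the
stem along the tonotopic axis: bifurcated iff min(e_a, e_b) >
0.05·(e_a+e_b), else the larger side.  Fiber density is total skeleton
length per kHz of span; puncta density is puncta per 100 µm of skeleton.
CALB2 selectivity is the fraction of puncta On-CALB2 (0 = all Off, 1 = all
On).  The correlation screen reports per-metric Pearson r with two-sided
t-based p values and, deliberately, no multiplicity correction.

## snRNA-seq QC

Filters compose in a fixed order (genes → cell floors → SD screen), each a
single pass.  Boundary semantics are strict: "fewer than 500 genes" removes
a 500-gene cell only if the floor is 500 and the rule is `nGenes > 500`
(the batch floors make the two printed phrasings coincide everywhere except
exactly at the boundary, where the strict reading governs).  The
mitochondrial metric defaults to mito-UMI share of total UMI — the standard
metric — with a `gene_fraction` option matching the literal "fraction of
detected genes" wording.  The 2-SD screen computes mean and SD once per
batch group on the post-floor population and is applied once, not
iterated; a raw-count scale is the default with a log10 option, since the
scale is a convention choice.

## Synthetic data: what it does and does not show

**LSO generator.**  Somata are non-overlapping disks (Gaussian radius
6±1 px, rejection-sampled, ≤ 1000 retries) inside an S-shaped polygon.
Expressing cells carry expected corrected intensity `intercept +
slope·position` plus *per-cell* Gaussian scatter (`noise_sd`, default
0.05 in normalized units) — the dominant variability in real sections is
biological cell-to-cell scatter, not shot noise.  Separate knobs add
per-pixel read noise (0.02) and a smooth random neuropil field
(low-pass-filtered noise, σ = 40 px, 50% relative amplitude around a 0.15
base level) that makes neuropil subtraction non-trivial.  Intensities are
rendered to 16-bit at 10⁴ counts per normalized unit.  Decoy objects
(disks outside the polygon; high-eccentricity slivers inside) exercise the
curation rules.  With all noise sources zeroed the measured corrected
intensity equals the planted value to within 16-bit quantization.

**Recovery studies.**  The slope-recovery study (3 planted slopes × 100
seeded replicates at n = 200 cells) feeds the generator's own label image
into measurement — the segmenter contract explicitly admits external label
maps — so it isolates measurement + normalization + regression; segmenter
quality is tested separately (every planted soma recovered at IoU > 0.5 on
clean images).  Because the pipeline divides by the brightest cell, the
planted slope is compared on that same scale (divided by the brightest
planted cell's intensity, which the ground truth records).  Coverage of
the adjusted CI is ≥ 90% per slope.  Passing these studies shows the
estimator chain is unbiased and honestly calibrated under the generative
model; it does not certify segmentation of real histology, antibody
variability, or section-to-section registration.

**Cochlea generator.**  A deterministic branched polyline axon (stem
entering perpendicular to a straight tonotopic axis — the unrolled cochlea;
all published metrics are along arc length, so curvature is omitted) is
rendered as a tube of radius 0.4 µm via an exact Euclidean distance field.
Syp puncta are spheres (0.5±0.05 µm) centered on the skeleton, ≥ 2 µm
apart, clipped to the axon tube.  NPY⁺ puncta are wrapped by an NPY sphere
0.2 µm larger; NPY⁻ puncta keep ≥ 2 voxels clearance from any NPY signal.
CALB2 "targets" are tubes perpendicular to the axon that overlap their
contact punctum by ~1.5 voxels, while non-contact puncta keep ≥ 2 voxels
surface gap — puncta whose prospective tubes would graze another punctum
are constrained to share a flag, so the planted flags are geometrically
unambiguous.  On noise-free volumes the pipeline recovers punctum count
and both flags exactly; at voxel noise 0.02 flag accuracy stays ≥ 95%.

**Counts generator.**  Healthy nuclei draw ~4000 UMI over ~800 (dev) or
~550 (adult) genes; planted failures violate exactly one rule each
(low-gene, low-UMI with genes above the floor, 5% mito load, or a 12×
outlier library), and rare genes appear in exactly 2 cells.  The QC
pipeline's survivors equal the planted expectation and a brute-force rule
oracle exactly.

## Numerical and reproducibility choices

All randomness flows from a single integer seed per run
(`numpy.random.default_rng`); identical parameters give bit-identical
images, masks and tables.  Study sub-seeds are derived arithmetically from
the top-level seed and kept below 2³¹.  Outputs carry JSON sidecars with
seed, config hash and package version.  Degenerate inputs fail loudly with
typed exceptions (geometry, placement, resolution, format, configuration,
insufficient data) rather than returning partial results; the two
documented soft cases are the blank-image segmenter (empty mask) and the
empty-neuropil fallback (flagged median background).

Known limitations: the built-in segmenter under-performs on dense or noisy
sections compared to learned segmenters (by design it is replaceable); the
covariogram-based CI needs enough cells (~dozens) per section to estimate
spatial covariance; the prolate-blob splitting heuristic bisects rather
than optimally partitioning multi-lobed clusters; SWC import assumes the
standard 7-column dialect in µm.
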