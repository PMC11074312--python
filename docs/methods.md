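# Methods

This note documents the models, defaults and numerical choices behind
`switchquant`, and what the synthetic benchmarks do and do not demonstrate.

## The measurement model

The pipeline's central object is the cell table: one row per segmented
nucleus with centroid (x = column, y = row, pixel centers at integer
coordinates, origin top-left), area, and the unweighted mean intensity of
every channel over the nucleus' pixels.  All downstream statistics are
defined on this table, so any segmentation backend that produces a label
image (including externally trained star-convex models, imported as 16-bit
label TIFFs) can feed the same analyses.  The built-in segmenter is
classical and fully deterministic: Gaussian smoothing (σ = 2 px), Otsu (or
manual) global threshold, hole filling, Euclidean distance transform,
peak markers (the distance map is smoothed with σ = 1 px first — touching
disks otherwise produce plateau maxima that duplicate or vanish), marker
watershed, then an area filter defaulting to [0.3, 3] × the median detected
area, which removes debris and merged blobs without requiring a pixel size.

Background is a scalar per image.  The default estimator is the median
pixel value: while foreground covers well under half the image the median
of the background distribution is recovered nearly unbiasedly, whereas a
low percentile is systematically below the mean background by a
noise-dependent offset (for Poisson noise at level b, the 25th percentile
sits ≈ 0.67·√b low).  A rolling-ball field estimator is available when the
background is not flat.  Fold-over-background is the ratio of the raw
nuclear mean to this estimate — a ratio, not a difference, so
driver-negative cells sit at fold ≈ 1 and the conventional 2× and 4×
thresholds are directly interpretable.

## The bistable switch statistics

ON/OFF classification fits a two-component Gaussian mixture to log
intensities (sklearn, k-means++ initialisation, 10 restarts, fixed seed,
EM tolerance 1e-6 with up to 1000 iterations — with overlapping components
the looser default tolerance stops short of the maximum-likelihood
solution and visibly biases the recovered state fractions).  Cells are
assigned by posterior ≥ 0.5; the ON component is the higher-mean one.  The
separation statistic D = |μ₁−μ₂|/√((σ₁²+σ₂²)/2) quantifies bimodality;
input with zero spread returns a single-population verdict with D = NaN
rather than an error.  The plain threshold classifier is inclusive
(fold ≥ cutoff ⇒ ON); a fixed convention is needed and ties at the cutoff
have measure zero in float data.

The dose–response curve bins cells by driver fold with right-open edges
(0, 1.5, 2, 4, ∞), labelled negative / low / 2–4× / ≥4×, and reports the
response-negative fraction per bin with a Wilson 95 % interval.  Bin counts
always partition the table; empty bins carry n = 0 and NaN fractions.
Channel correlation defaults to log10 intensities, since fluorescence spans
orders of magnitude.  Equal-count gating ranks cells by a channel (stable
sort, ties broken by input order) and cuts into three contiguous rank
groups; when n is not divisible by 3 the extra cells go to the lower gates.

## Spatial packing

Nearest-neighbour distances use a k-d tree (exactly equal to the all-pairs
definition); the comparison between conditions is the two-sample KS test
plus medians.  Distances are in pixels unless a pixel size is given.  No
border-edge correction is applied: nuclei near the image edge can only have
neighbours on one side, which biases their NN distance upward.  This bias
is shared by both conditions in a comparison but should be kept in mind for
absolute values.

## smFISH quantification

The stack is filtered with a scale-normalised, negated Laplacian of
Gaussian (σ defaults to 1.5 px, the diffraction-limited spot scale at high
magnification), *then* projected by per-pixel maximum over z, and spots are
called as local maxima above median + k·MAD of the projected filtered
image.  The default k = 10: the projection keeps the maximum noise
excursion over z per pixel, so its extreme-value tail reaches roughly
10 MAD on typical stacks while true spots at SNR ≈ 10 respond at ≳ 45 MAD;
k = 10 sits between the two on a log scale.  Non-maximum suppression
defaults to 2 px (≈ 1.3 σ), the smallest radius that still merges
sub-resolution doublets.  Each spot inherits the segmentation label under
its (x, y); label 0 is the explicit unassigned bucket, so assigned +
unassigned always equals total detections.

## Peak-to-gene assignment and the overlap bootstrap

Every gene receives a strand-aware basal regulatory domain (default 5 kb
upstream to 1 kb downstream of the TSS, half-open coordinates, BED-style
0-based throughout) extended in both directions toward the neighbouring
genes' basal domains up to 1 Mb from the TSS; extension never cuts into a
gene's own basal domain.  A gene "has a peak" when any peak interval
overlaps its domain (half-open overlap).  The enrichment test counts
peak-bearing genes in the differentially expressed set, then draws equally
sized random gene *sets* from the universe (without replacement within a
draw — the null models a gene list, not independent picks; with-replacement
sampling is available) for 10,000 iterations by default.  Fold enrichment
is observed / null mean; the empirical p-value is (r+1)/(B+1) with r the
number of null draws at or above the observed count, so p can never be
exactly zero.  The null mean converges to the hypergeometric expectation
n·K/N.  The choice of gene universe (all annotated genes vs. expressed
genes) changes K/N and is deliberately an explicit input with no default.

## qPCR statistics

N0 starting quantities are inputs (amplification-curve fitting is prior
art and out of scope).  Each target N0 is divided by the geometric mean of
the housekeeping N0s of the same sample — any common per-sample factor
cancels — then log₂-transformed (base 2 is the convention for expression
fold changes) and centred on the mean of the control condition's
replicates, so the control averages exactly zero per gene.  Relativisation
happens after the per-sample ratios, before any averaging across
conditions.

The randomized-block ANOVA is the balanced two-way additive decomposition
(condition + block, one observation per cell, no interaction), computed in
closed form; complete blocks are required and never imputed.  The closed
form is exact for this design and is cross-checked against a linear-model
fit in the test suite.  Tukey's HSD uses the blocked mean square error with
the studentized range distribution (k groups, (k−1)(b−1) error df);
statsmodels' stand-alone Tukey helper ignores the block term, which is why
the contrasts are computed here.  Because Tukey significance depends only
on the distance between means, the mutually non-significant sets are
contiguous runs of the mean-sorted conditions; each maximal run receives
one letter of the compact letter display.  When all condition means
coincide exactly, F is reported as 0 with p = 1 and a single shared letter.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, with
known ground truth:

* **Geometry.**  Nuclei are hard disks (radius 9 ± 0.8 px by default) with
  a 1-px Gaussian edge blur — the simplest shape with unambiguous
  segmentation truth.  Tight mode packs centers into colony disks sized for
  a 0.32 area fraction at minimum center separation 2 × radius (random
  sequential placement saturates not far above this fraction);
  spread mode inflates the colony disk 1.8× and detaches 20 % of each
  colony's nuclei as singletons scattered over the image.  Placement is
  dart throwing with a gradually relaxed colony-separation constraint;
  an image genuinely too small for the request fails loudly, naming the
  constraint.
* **Expression.**  Channel levels are log-normal in *fold-over-background*
  units: OFF components have log-mean 0 (fold ≈ 1), the driver ON
  component log-mean ln 3 with log-sd 0.9 (a wide induction spanning the
  negative through ≥4× bins), the response ON component log-mean ln 8 with
  log-sd 0.4 (a clearly bimodal marker), background level 100 counts.
  70 % of cells are driver-positive.  The response state is Bernoulli with
  P(ON) from the repressive Hill link (defaults F₁⁄₂ = 2, h = 6, i.e. the
  half-repression point at two-fold background and a steep switch).
* **Noise.**  Poisson shot noise on the expected signal plus additive
  Gaussian read noise (sd 2), stressing background estimation the way real
  fluorescence statistics do.
* **Spots.**  3-D isotropic Gaussians (σ 1.5 px, amplitude 200 on baseline
  100 with noise sd 20 ⇒ SNR 10) at subpixel positions inside eroded cell
  masks, with a minimum in-plane separation of 4 px: the detection
  benchmark is defined over *resolvable* spots.  Counts per cell follow a
  (mean, dispersion) family — dispersion 0 is deterministic, 1 Poisson,
  > 1 negative binomial — or can be pinned per cell to couple transcript
  numbers to a simulated expression state.
* **Gene universes.**  TSSs are placed uniformly with a minimum spacing
  wider than one basal domain, and each flagged gene receives a peak just
  downstream of its TSS, inside its own basal domain and outside every
  neighbour's reach — so the assignment rule recovers the planted flags
  exactly, by construction.

Everything is reproducible bit-for-bit from the seeds; derived seeds come
from `numpy` `SeedSequence` spawning.

**What the generator does not emulate:** photorealistic optics (PSF,
uneven illumination, chromatic shifts), 3-D nuclear shape, cell-cycle or
temporal dynamics, autofluorescence, spectral bleed-through, segmentation
errors of irregular nuclei, unresolvable transcript doublets, or any
correlation structure between genes beyond the planted peak flags.
Passing benchmarks therefore demonstrates correctness of the *algorithms*
under the stated statistical model, not performance on real micrographs;
on real data the segmentation and spot-detection accuracy will be lower
and should be re-validated per dataset.

## Benchmark problem sizes

The bundled benchmarks use: 5 × 100-nucleus images for segmentation;
300 nuclei per condition for the packing contrast; 5,000 cells for
dose–response recovery; 20 mixtures of 1,000 cells (true separation D of
3, 5 and 10; ON fractions 0.3/0.5/0.7) for classification; a 1,000-gene
universe with 137 flagged genes, 292-gene draws and 10,000 bootstrap
iterations; 200 spots over 10 large (28 px) cells at SNR 10; and 1,000
null simulations of a 4-condition × 3-block design for ANOVA calibration.
These sizes give the relevant statistics sampling errors comfortably below
the assertion tolerances while keeping a full run in the low minutes on
one core.

## Known limitations

* The watershed segmenter assumes roughly convex, similarly sized nuclei;
  heavily elongated or overlapping (> ~30 %) nuclei merge or split.
* The scalar background model ignores illumination gradients; use the
  rolling-ball method or flat-field correction upstream when they matter.
* NN-distance distributions carry the uncorrected border bias above.
* The GMM classifier's hard assignment is biased toward the majority
  component when separation is marginal (D ≲ 3); at D = 3 expect ON-
  fraction errors up to a few percentage points.
* The regulatory-domain rule is a local re-implementation of the published
  basal-plus-extension convention; curated regulatory domains from the
  original web service can differ near chromosome ends and gene-dense loci.
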