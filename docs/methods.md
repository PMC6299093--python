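# Methods

## SMLM colocalization statistic

**Model.** Each channel's localizations (continuous nm coordinates) are
clustered with DBSCAN (defaults `eps = 75 nm`, `min_pts = 5`; both in
config). Upstream localization software emits emitter positions only, so
the clustering algorithm is a design choice of this package; DBSCAN was
chosen because nuclear foci are compact, high-density structures on a
sparse background and density-based clustering needs no preset cluster
count. Each cluster is summarized by its centroid (member mean) and an
*effective radius* equal to the maximum member distance to the centroid, so
the disc covers every member localization; a radius-of-gyration variant is
available (`radius_mode="gyration"`) for sensitivity analysis.

**Overlap criterion.** Two clusters overlap when their centroid distance is
at most the sum of their effective radii (disc intersection). This operates
on continuous cluster geometry rather than rendered pixels: it is invariant
to rendering choices and admits an exact analytic null for testing.
Overlaps are counted as unordered intersecting *pairs* (symmetric in the
two channels); a matched-cluster counter (`unit="matched"`) is provided for
comparison. Rendering (20-nm pixels by default) is retained for
visualization/QC only.

**Randomization null.** Per nucleus, 20 Monte-Carlo simulations each
translate *every* cluster of *both* channels to an independent uniformly
random position whose disc lies wholly inside the nucleus ROI (centroid
uniform over the ROI eroded by the cluster radius; rejection sampling for
polygons, distance-transform thresholding at pixel precision for raster
masks). Rearranging both channels makes the baseline sensitive to both
channels' cluster numbers and size distributions — this is how the broader
spatial spread of a damage marker such as γH2AX is accounted for relative
to compact hybrid foci; single-channel randomization remains available
(`randomize="single"`). Clusters are never rotated or reshaped, and no
hard-core exclusion is imposed between randomized clusters. The normalized
ratio divides real overlaps by the mean of the 20 random counts. Nuclei
whose null never yields an overlap cannot be normalized: with real overlaps
present they are flagged `null-degenerate` and excluded from cohort
statistics (the count is reported); with neither real nor random overlaps
the ratio is defined as 0 and flagged.

**Degenerate geometry and determinism.** When erosion by the cluster radius
leaves no area (e.g. a disc-shaped ROI of exactly the cluster radius) the
cluster is placed at the ROI's pole of inaccessibility, with 0.1% clearance
slack to absorb polygonal approximation of curved boundaries; a radius
exceeding the ROI inradius raises a placement error naming the cluster's
geometry. One root seed drives a run; each nucleus gets a child stream
derived by SHA-256 hashing of its id, so adding or removing nuclei never
perturbs the others' results. Rejection candidates are drawn in the unit
square and mapped onto the eroded bounding box, making the statistic
exactly invariant under uniform rescaling of all coordinates.

**Cohort summary.** Group means ± s.e.m. over per-nucleus ratios, and a
Welch two-sample two-tailed t test between two groups (withheld with a
warning when a group has fewer than two valid nuclei; two constant equal
groups return t = 0, p = 1).

## DSB-proximal enrichment profile

Coordinates are 0-based half-open throughout; the cut position is the
0-based coordinate of the break (midpoint of wider BED features). Count
tracks are RPKM-normalized per bin — `count / ((len/1000) · (total/10⁶))`,
using each bin's actual length — with library sizes defaulting to the track
totals. The ratio track is `log2(cut + c) − log2(uncut + c)` with
pseudocount `c = 1` on the normalized scale (configurable); computing it as
a difference of logarithms makes swapping the conditions negate every bin
bitwise. The top-k sites (default 50) are selected by cleavage score with
deterministic (chrom, position) tie-breaking.

Window assignment uses absolute distance, pooling the left and right
footprints `[pos−upper, pos−lower) ∪ [pos+lower, pos+upper)` per window
(a signed-distance analysis can be built by passing single-sided windows).
A bin is assigned iff its overlap with the footprint is ≥ 90% of the bin
width; the comparison is `≥` with a 10⁻⁹ bp guard against float round-off,
so a 45-bp overlap of a 50-bp bin passes exactly and 44 bp does not. Since
adjacent windows partition the footprint, overlap fractions across windows
sum to ≤ 1 and a bin can satisfy the rule for at most one window per site
whenever the threshold exceeds 0.5 (asserted at runtime). Sites are treated
independently, so one bin may serve several sites. Per-(site, window) means
with zero assigned bins are omitted and counted.

The Wilcoxon signed-rank test is one-sample against 0 on per-site window
means (a paired cut-versus-uncut variant can be assembled from the two
normalized tracks); zero differences are dropped. The null is exact for
n ≤ 25 without ties among absolute differences and a normal approximation
with continuity correction otherwise; the exact branch is verified against
full 2ⁿ enumeration in the tests. No multiple-testing correction is applied
by default (per-window p-values are reported side by side, as in standard
per-window annotation); Bonferroni over the five windows is available via
`bonferroni=True`. Tests are withheld for windows with fewer than 5
contributing sites.

## qPCR arithmetic

Percent input is `100 · IP / (input / input_fraction)`; `input_fraction`
(the chromatin fraction set aside as input) has no canonical default and
must be supplied. Cq values convert to linear quantities as
`efficiency^(−Cq)` with efficiency fixed at 2.0 fold/cycle by default
(configurable per assay). Fold induction is computed per replicate and then
averaged with s.e.m. across replicates — not as a ratio of means — matching
per-experiment fold reporting. ΔΔCq relative expression is
`efficiency^(−[(Cq_t − Cq_n) − (Cq_t,ref − Cq_n,ref)])`, invariant to
constant Cq shifts applied to both target and normalizer. Failed wells
(zero input or uncut) yield NaN flags rather than errors so replicate
tables aggregate gracefully.

## Synthetic data: what it emulates, and what it does not

**SMLM generator.** Defaults are the reference imaging geometry used by the
cohort analyses: a 10 × 10 µm nucleus, 40 clusters per channel of 100 nm
radius (radius s.d. 0), ~30 localizations per cluster (Poisson), no
background. Colocalization is modelled at the *cluster* level — a fraction
`f` of channel-B centroids is placed at randomly chosen channel-A centroids
plus Gaussian jitter (σ = 50 nm, well inside the 200-nm overlap reach of
two 100-nm discs) — because it is clusters that the statistic randomizes
and counts. Member localizations are Gaussian (σ = r/2) truncated at the
cluster radius. All centroids are drawn uniformly over the ROI eroded by
the cluster radius, the same admissible domain the randomization null uses,
so the null calibration is exact rather than edge-biased. The generator
does not emulate camera/PSF physics, drift, repeated blinking of single
emitters, or chromatic offsets; passing tests therefore validate the
statistic and its null, not robustness to those acquisition artifacts.

**Coverage generator.** One 100-Mb chromosome with 50 cut sites at least
5 kb apart (twice the outermost window, keeping window footprints
disjoint); fold enrichment rises piecewise-linearly from 1 at the break to
3 at 1.5 kb and returns to 1 by 3 kb, the canonical hybrid-accumulation
shape around a resected break. Bin counts are negative binomial with mean
100 per 50-bp bin and size 50 — the mild technical overdispersion expected
between two sequencing libraries of the same sample pool (biological
replicates would be far more dispersed, but cut/uncut tracks are single
library pairs). The chromosome is long enough that the enriched footprints
are a negligible fraction (~0.3%) of the library, as in a real genome;
on a short chromosome the enriched mass itself would distort total-count
normalization and impose a spurious negative baseline. The scrambled-site
control redraws site positions outside all true enrichment footprints
(matched random undamaged regions). Read-level effects — mappability, GC
bias, fragment-length smoothing — are not simulated.

**qPCR generator.** IP quantities carry independent mean-one log-normal
noise of stated CV; input quantities are treated as exactly measured, since
input material is abundant and its measurement CV is negligible against the
IP's. Per-replicate fold ratios of log-normals carry a small convexity bias
(e^{σ²} ≈ +4% at CV 0.2), which the arithmetic per-replicate-then-average
estimator inherits; this is a property of ratio estimation, not a defect of
the recovery, and stays within the 5% envelope used in the checks.

## Problem sizes and numerical choices

The shipped checks use 200 nuclei for null calibration, 50 per
colocalization level, 10⁴ draws for placement uniformity, 10⁴ bins × 20
sites for assignment-oracle equivalence, one 100-Mb simulated experiment
(2 × 10⁶ bins) for profile recovery, and 200 seeds × 6 replicates for fold
recovery — sizes at which every Monte-Carlo band in the tests is several
standard errors wide. Floating-point guards: the 90% overlap comparison
uses a 10⁻⁹ bp tolerance; radii are grouped at 10⁻⁶ nm for randomization;
boundary localizations count as inside (floor-pixel rule for masks,
inclusive polygon boundaries). Welch tests special-case zero pooled
variance; chi-square and signed-rank checks use two-sided p-values unless
stated.

## Known limitations

- Two channels only; no Pearson/Manders-style rendered-image correlation.
- Raster-ROI erosion is resolved at pixel precision; very fine masks with
  pixel size comparable to cluster radii will quantize admissible regions.
- The enrichment stage takes cleavage ranks as given and performs no
  alignment, duplicate removal, or peak calling.
- The per-nucleus ratio is undefined when the randomization null is empty;
  such nuclei are reported but cannot enter cohort statistics.
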