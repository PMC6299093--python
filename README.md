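# dsbquant

Quantification pipelines for studying DNA:RNA hybrids and repair factors at
DNA double-strand breaks (DSBs), written for imaging and genomics analysts
who need the bespoke statistics of this field as tested, reusable code:

1. **SMLM colocalization with a cluster-randomization null**
   (`dsbquant.smlm`, `dsbquant.coloc`). In two-channel single-molecule
   localization microscopy (STORM) of, e.g., γH2AX versus S9.6-detected
   DNA:RNA hybrids, foci are detected per channel by density-based
   clustering of the localizations. An *overlap* is a pair of clusters
   (one per channel) whose discs — centroid ± effective radius — intersect.
   Chance colocalization is estimated per nucleus by Monte-Carlo
   rearrangement: every cluster of both channels is translated to an
   independent uniform admissible position inside the nucleus ROI
   (preserving each cluster's size and localization count) and overlaps are
   recounted. With real count *n*ᵣₑₐₗ and random counts *n*₁…*n*ₖ
   (*k* = 20 by default),

   normalized overlap ratio = *n*ᵣₑₐₗ / mean(*n*₁…*n*ₖ),

   ≈1 for independent channels, >1 for true colocalization. Because both
   channels are rearranged, channel-specific cluster sizes and numbers
   (e.g. the broad γH2AX spread) propagate into the baseline.

2. **DSB-proximal enrichment profiles from binned coverage**
   (`dsbquant.enrichment`). Cut/uncut coverage in 50-bp bins is
   RPKM-normalized, converted to per-bin log₂((cut+c)/(uncut+c)), and
   aggregated around the top-50 ranked cut sites into five absolute-distance
   windows (0–0.5, 0.5–1, 1–1.5, 1.5–2, 2–2.5 kb; both sides pooled). A bin
   counts toward a window only if ≥90% of the bin lies in the window's
   genomic footprint. Per-site window means are summarized (boxplot
   quartiles) and tested against 0 with a one-sample Wilcoxon signed-rank
   test — exact (full 2ⁿ enumeration) for n ≤ 25 without ties — overall and
   split by genic/nongenic site status.

3. **qPCR arithmetic** (`dsbquant.qpcr`): percent input
   (100·IP/(input/input-fraction)), cut/uncut fold induction computed per
   replicate then averaged (mean ± s.e.m.), and ΔΔCq relative expression.

`dsbquant.simulate` generates synthetic inputs with the statistical
structure each stage assumes (clustered two-channel point patterns with a
controllable colocalized fraction; negative-binomial bin counts with a
fold-enrichment profile peaking at 1.5 kb from the break; replicated
log-normal qPCR measurements), so everything is testable with no external
data.

## Worked example

```python
import numpy as np
from dsbquant import coloc, simulate as sim

spec = sim.SmlmSimSpec(coloc_fraction=0.6)          # 60% of S9.6 foci seeded at γH2AX foci
nuc = sim.simulate_smlm_nucleus(spec, nucleus_id="cell01", rng=7)

a = coloc.detect_clusters(nuc.table, channel="gH2AX", roi=nuc.roi)
b = coloc.detect_clusters(nuc.table, channel="S9.6", roi=nuc.roi)
res = coloc.normalized_overlap_ratio(a, b, nuc.roi, n_sim=20, seed=7)
print(f"clusters: {res.n_clusters_a} gH2AX, {res.n_clusters_b} S9.6")
print(f"real overlaps: {res.n_real_overlaps}")
print(f"mean random overlaps (20 simulations): {res.mean_random:.2f}")
print(f"normalized overlap ratio: {res.normalized_ratio:.2f}  [{res.flag}]")
```

prints

```
clusters: 39 gH2AX, 30 S9.6
real overlaps: 19
mean random overlaps (20 simulations): 2.20
normalized overlap ratio: 8.64  [ok]
```

i.e. in this nucleus the two channels overlap 8.6× more often than expected
if their foci were scattered at random — strong colocalization, as designed
into the simulation. Under an independent-channels simulation
(`coloc_fraction=0`) the ratio concentrates around 1.

The same analyses are scriptable from the shell:

```sh
dsbquant simulate smlm --n-nuclei 20 --seed 1 --out sim/
dsbquant coloc run --locs sim/localizations.csv --roi-dir sim/rois \
    --channels gH2AX,S9.6 --seed 1 --out coloc_out/
dsbquant simulate drip --seed 1 --out drip/
dsbquant drip-profile --cut drip/cut.bedgraph --uncut drip/uncut.bedgraph \
    --sites drip/sites.bed --top 50 --out profile/
```

Every output directory contains a JSON run manifest (parameters, seed,
input digests) sufficient to reproduce the run bit-identically.

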