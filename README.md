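# censpa — single-particle averaging of mitotic centromere geometry

Human centromeres direct kinetochore assembly and hold sister chromatids
together through mitosis, but the individual structures are small and
variable: a single 3D-SIM image of one centromere is too noisy to measure
its architecture.  `censpa` implements the single-particle-averaging (SPA)
approach for this problem: hundreds of centromeres from metaphase spreads
are detected, rotationally aligned on their sister CENP-A clusters, and
summed, so that average distances and widths can be read off sub-resolution
from Gaussian fits of the pooled image.  The package targets the core
geometry of the mitotic centromere: the spacing of sister CENP-A clusters
(~562 nm, S.D. 91.6 nm across particles), the pericentromeric cohesin axis
between them (lateral S.D. ~190 nm, extending ~800 nm along the
chromosome), and the surrounding α-satellite DNA cloud (weak lateral peaks
at ±209 nm flanking a shallow 411 nm-wide central dip; the chromosome-7
D7Z1 array at ±206 nm with a wider 634 nm CENP-A spacing).

Because raw microscopy data are not redistributable, the package ships a
forward model: a synthetic-image generator whose defaults encode the
measured geometry above.  Every pipeline stage is then verifiable by
parameter recovery — simulate a spread with known truth, run the pipeline,
and check that the recovered numbers match the configured ones.  A separate
module implements the genomic side of the analysis: replicate-consensus
ChIP peaks, peaks-per-Mb densities across centromeric region classes,
fragment proportions, random control regions and peak-overlap fractions,
all on BED-style intervals.

## Method

For each centromere the pipeline:

1. detects CENP-A clusters as local maxima of the smoothed 3D stack and
   pairs them into sister doublets by mutual nearest neighbours within a
   200–1200 nm gate;
2. refines each cluster center by least-squares fitting of a 3D Gaussian
   (isotropic in *xy*, separate *z* width) plus offset, giving sub-pixel
   centers, the per-particle separation *d* = ‖**c**₂ − **c**₁‖ and the
   in-plane angle θ of the inter-sister axis;
3. rotates the center *z*-slice by −θ about the pair midpoint, crops a
   60 × 60 px patch centered on the midpoint, appends the left-right mirror
   of every patch (slide orientation is random), and sums;
4. extracts band-integrated profiles (5 px = 200 nm band at the 40 nm
   pitch; 41 px for the CENP-A axial width) along the lateral and
   chromosomal axes and fits *k* = 1–3 Gaussians plus offset, selecting *k*
   by the Akaike information criterion for least squares,
   AIC = *n* ln(RSS/*n*) + 2(3*k* + 1), ties resolving to fewer peaks;
5. classifies each particle's cohesin pattern by the center-enriched ratio
   (mean intensity |y| ≤ 120 nm over 160 ≤ |y| ≤ 320 nm along the
   chromosomal axis), ranks ascending, partitions at the 200/150/113 rank
   boundaries into split / uniform / central classes, and compares
   inter-CENP-A distances across classes with a Kruskal–Wallis test (Dunn
   post-hoc, Benjamini–Hochberg adjusted).

## Worked example

```bash
python examples/01_simulate_and_measure.py
```

```
particle attrition: {'detected': 160, 'paired': 80, 'orphans': 0, 'refined': 80, 'aligned': 80}
inter-CENP-A distance (fit):     556.2 nm  (truth 562)
per-particle separation S.D.:     95.0 nm  (truth 91.6)
CENP-A cluster S.D.:              80.9 nm  (truth 81)
cohesin lateral S.D.:            190.1 nm  (truth 190)
cohesin axial extent (FWHM):     799.6 nm  (truth 800)
```

Eighty synthetic centromeres were rendered with default noise, every one
was detected, paired, refined and aligned, and the fitted average image
returns the configured geometry to a few nanometres (the residual spread is
finite-sample: 80 particles at 91.6 nm jitter).  The other examples cover
cohesin-pattern classification (`02`), the α-satellite FISH presets (`03`)
and the interval peak-density analysis (`04`).  A thin CLI wraps the same
stages (`censpa simulate | detect | average | profile | classify | density |
run-all`).

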