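# Methods

## Forward model

A synthetic centromere is three co-registered channels rendered as smooth
intensity fields sampled at voxel centers (pixel *i* at (*i* + 0.5)·pitch;
40 nm/px laterally, 125 nm z-steps, 9 slices, 60 px crops by default —
"OMX" preset; an "Elyra" preset sets 31 nm/100 nm).  In the particle frame
(*u* lateral, *v* chromosomal):

- **CENP-A**: two isotropic 3D Gaussians at *u* = ±*d*/2, with the
  separation *d* drawn per particle from N(562, 91.6²) nm and the in-plane
  angle uniform on [0°, 360°).
- **cohesin marker**: G(*u*; σ = 190 nm) × B(*v*) × class modulation,
  where B is an 800 nm top-hat convolved with a 50 nm Gaussian (smooth
  shoulders; FWHM exactly 800 nm).  Classes modulate the band by
  1 − 0.7·G(*v*; 120 nm) ("split"), 1 (uniform) or 1 + 1.0·G(*v*; 120 nm)
  ("central").  Optional minor flanking pools at *u* = ±381 nm (off by
  default) reproduce the three-peak lateral profile seen with signal
  amplification.
- **satellite marker** (FISH presets): the sum of two equal Gaussians at
  *u* = ±209 nm whose common width is solved numerically at configuration
  time so that the two maxima of the summed profile sit 411 nm apart
  (σ = 134.1 nm); the chr7 preset instead fixes σ = 175 nm at ±206 nm with
  a 247 nm chromosomal spread and draws separations from N(634, 102²).
- **DNA (DAPI)**: a diffuse ellipse (σ 350 × 700 × 300 nm), qualitative
  only.

Noise is Poisson shot noise (configurable photons per intensity unit) after
adding a constant background, then additive Gaussian read noise.  Defaults
— peak expected counts of 300 (CENP-A), 200 (marker), 60 (DNA) over a
background of 10, Poisson scale 1, read noise σ = 2 — are typical of
reconstructed 3D-SIM spread data; the paper quantifies geometry, not
photon budgets, so these are the package's own realism choices.  Identical
seed and configuration give bit-identical stacks.

### Calibration choices

Two generator parameters are *derived* rather than taken verbatim, because
the quantities they control are measured downstream of alignment:

- **Cluster width.**  The 81 nm CENP-A cluster S.D. is an ensemble value
  read off the summed average image.  Alignment centers each particle on
  its pair midpoint, so the per-particle separation jitter (S.D. 91.6 nm)
  smears each cluster by 45.8 nm in the average.  The generator therefore
  renders clusters at √(81² − 45.8²) = 66.8 nm so that the pipeline
  recovers *both* the 81 nm ensemble width and the 91.6 nm separation S.D.
  With zero configured jitter the rendered width equals the configured
  width.
- **Satellite dip width.**  The central depression's "width" is
  operationalized as the distance between the two profile maxima flanking
  the central minimum.  A full-width-at-half-depth reading is not usable
  here: for any smooth two-peaked profile with maxima at ±209 nm the
  half-depth width cannot approach 411 nm (it reaches 2 × 209 only in the
  limit of needle-thin peaks; realistic widths give ≈200 nm).  The
  inter-maxima distance is well defined, reaches 411 nm at σ = 134 nm, and
  is consistent with a *shallow* dip between *weak* peaks.  The
  measurement routine reports the same quantity, from the AIC-selected
  fitted model with parabolic refinement of the maxima.

## Pipeline numerics

- **Detection**: Gaussian smoothing (σ = 1 px), local maxima above the
  0.999 intensity quantile, non-maximum suppression within 3 px.  Constant
  images yield no peaks.
- **Pairing**: mutual nearest neighbours in 3D (nm), gate 200–1200 nm
  (brackets 562 ± 91.6 and 634 ± 102 at > 4 S.D.).  Equal-distance ties go
  to the higher-intensity partner; pairing is order-invariant.
- **Refinement**: trust-region least squares of amp·G₃(center, σ_xy, σ_z)
  + offset in an 11 px window (all z).  Fits that fail to converge or whose
  center escapes the window are dropped and logged; refined pairs leaving
  the separation gate are dropped.
- **Alignment**: the z slice nearest the fitted midpoint is rotated by −θ
  about the midpoint and resampled onto the 60 px crop with cubic-spline
  interpolation (order 1 available); for the even crop the midpoint maps
  onto the corner shared by the four central pixels, so patch coordinates
  (*i* + 0.5 − crop/2)·pitch are symmetric about zero and the left-right
  mirror is an exact index reversal.  Patches sampling outside the field
  are zero-padded and edge-flagged.  Sums (not means) are stored; all
  profile shapes are invariant to that choice.
- **Profiles**: a band of `width_px` rows/columns nearest the midline
  (ties to the lower index), summed.  5 px ↔ 200 nm at the 40 nm pitch;
  41 px for the CENP-A axial width.
- **Gaussian fits**: k = 1–3 components plus offset; initial centers from
  the k largest local maxima (symmetric fallback positions otherwise);
  σ bounded below by one sample spacing (narrower peaks are unresolvable
  and would let single noise samples masquerade as structure); AIC =
  n·ln(RSS/n) + 2(3k+1), no small-sample correction (n ≈ 60; the
  correction changes no decision in the test suite).  RSS is floored at
  10⁻¹⁴·Σy² so that numerically exact fits of different order tie, and
  ties resolve to fewer peaks.  Headline pair distances (inter-CENP-A,
  satellite peak offset) use the two largest-amplitude components, so a
  small residual component retained by AIC cannot displace a structural
  peak.
- **Derived measures**: widths are reported as Gaussian S.D. (FWHM =
  2.3548σ additionally available); the cohesin axial extent is the FWHM of
  the chromosomal-axis profile (the ~800 nm figure is not otherwise
  defined); per-particle inter-CENP-A distances come from refined centers,
  the population value from the averaged-image fit — both are reported.

## Classification

The center-enriched ratio is mean intensity at |y| ≤ 120 nm over
160 ≤ |y| ≤ 320 nm (6 px ↔ 240 nm anchors the off-center band).  Low ratio
= center-depleted ("split"); this direction matches the published rank
anchors (ratio 0.0861 → rank 1 → split), and the written description's
inverse ratio is available as `mode="methods_literal"`.  Default partition
boundaries are the published rank spans 200/350 out of 463 (an
equal-thirds option exists); class sizes are always reported explicitly.
Across-class separation comparisons use Kruskal–Wallis with Dunn post-hoc
z-tests, Benjamini–Hochberg adjusted; with fewer than two populated
classes the test is skipped with a logged notice.

## Interval analysis

Intervals are 0-based half-open; chromosome sizes come from a two-column
table.  Consensus peaks are the union-merge of all replicate peaks,
filtered to loci overlapped by ≥ 2 distinct replicates.  Peak-to-region
assignment defaults to the midpoint rule — it makes labels a partition, so
counts are additive — with any-overlap as an alternative.  log2 of a zero
density is reported as NaN and excluded from summaries; pseudocounts would
distort cross-class comparisons.  Random control regions default to 2 Mb
(the flanking-region scale; the source length is unstated) and are drawn
uniformly over allowed start positions with rejection against the
exclusion set, deterministically under a seed.

## What the synthetic data does and does not show

The generator reproduces the *average* geometry and its particle-to-particle
jitter, Poisson + read noise, random orientation and class mixtures.  It
does not model SIM reconstruction artifacts, out-of-plane tilt of the
inter-sister axis (a z-offset field exists but defaults to 0), chromatid
arm morphology, overlapping or touching centromeres, or intensity
variation between spreads.  Passing recovery tests therefore demonstrates
that the pipeline is unbiased and precise on data matching its model
assumptions — not that those assumptions hold for any particular
microscope.

## Problem sizes and determinism

Recovery checks use n = 400 simulated particles (all-chromosome and CENP-B
presets), n = 200 (chr7) and n = 463 at the 200/150/113 class mix; the
null calibration of the class comparison uses 50 seeded draws of 463
separations.  These sizes match the scale of the source data (463 and 494
chromosomes; 33 for chr7) while keeping a full run in minutes on one CPU.
All randomness flows from explicit seeds; repeated runs are byte-identical.

## Known limitations

- The cohesin class modulation shapes (Gaussian dip/enhancement at
  σ = 120 nm, depth 0.7, enhancement 1.0) reproduce the qualitative
  ordering of the published montage, not fitted values.
- The CENP-B channel is modelled with peaks at ±209 nm; the alternative
  ±300 nm reading of the same figure is noted but not modelled.
- Peak calling, read alignment and FISH/IF wet-lab steps are out of scope;
  the interval module starts from called peaks.
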