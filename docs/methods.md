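# Methods

## The screen being quantified

An arrayed membrane yeast two-hybrid (MYTH) screen tests one membrane *bait*
protein against a library of *prey* fusion proteins. Bait–prey strains are
mated, diploids are selected on one plate series (96-spot format; colony
**area** there measures mating success), and each diploid is then pinned in
technical quadruplicate onto selective test plates (384-spot format) where
reporter-gene activation lets colonies grow: per-spot colony **density** on
the test plate is the quantitative interaction readout.

The pipeline turns plate photographs into interaction calls in five stages:

1. **Grid fitting** locates the spot-centre lattice on each plate image.
2. **Density/area extraction** integrates above-background intensity per
   test spot and counts thresholded foreground pixels per diploid spot.
3. **Normalization** min–max scales diploid areas over the whole screen and
   divides each test density by its source well's normalized area, so weak
   mating does not masquerade as weak interaction.
4. **Calibration and calling**: the positive cutoff is the 25th percentile
   of densities of colonies manually categorized as "weak" interactions; a
   prey is positive when at least half of its replicate spots are strictly
   above the cutoff.
5. **Comparison**: replicate agreement (intersection-over-union of hit sets,
   Pearson correlation of densities), per-bait two-fold enrichment, Venn
   partitions, hypergeometric annotation-term enrichment against the library
   background (Bonferroni over terms with ≥ 1 annotated hit), and row-wise
   hierarchical clustering (Euclidean, complete linkage) for heatmaps.

A companion module implements the nuclear-envelope GFP quantification recipe
for confocal z-stacks (projections, rolling-ball background subtraction,
blur + IsoData threshold, particle filtering by area and circularity, mean
intensity per nucleus on the sum projection).

## Definitions and conventions

* **Colony density** is the integrated above-background intensity over a
  disc of radius 0.45 × pitch centred on the spot, with the local background
  taken as the median of the window-corner pixels (distance > 0.52 × pitch).
  Integrated intensity is monotone in both colony size and opacity and is
  linear in the generator's ground truth, which is what makes an exact
  recovery oracle possible. Negative integrals clamp to zero. The local
  (per-spot) background makes measurements robust to smooth illumination
  gradients; a single global background would not be.
* **Grid fitting** estimates each axis of the lattice by template matching:
  candidate (pitch, origin) pairs are scored by the projection profile's
  local contrast at the n lattice positions (value minus the mean of the two
  half-pitch-away valleys). The contrast form cancels smooth gradients to
  first order, and because even non-interacting spots carry faint residual
  growth, every lattice position contributes — this keeps the fit anchored
  on sparse plates where only a few percent of spots are bright. Centres are
  then refined to the intensity centroid of above-half-maximum pixels
  (the colony plateau) within a half-pitch window; windows without signal
  5 robust SDs above their background keep the lattice position. Plates with
  no detectable spots raise a low-signal error with a manual origin/pitch
  override, except inside the screen composition, where a fully blank plate
  (total mating failure) falls back to a centred nominal lattice so that
  every expected spot is still reported.
* **Diploid areas** use one global Otsu threshold per plate. Otsu always
  splits *something*, so the threshold must clear the image median by three
  robust SDs, otherwise the plate is treated as featureless (all areas 0).
* **Min–max normalization** maps areas onto [0, 1] per screen (all plates of
  one bait pooled; per-plate scoping is available by calling per plate). The
  all-equal degenerate case maps to 1.0. Because the minimum-area well maps
  to exactly 0 — where the division is undefined — wells with normalized
  area < ε (default 0.05) or zero absolute area are flagged `failed_mating`
  and excluded from calling rather than divided; absence of a diploid is not
  evidence of absence of an interaction, so these prey are reported with a
  `no_call` status, never as negatives.
* **Quadruplicate geometry**: 96-well (r, c) expands to the contiguous 2×2
  block {(2r−1, 2c−1) … (2r, 2c)} in 384 format — standard replicate-pinning
  geometry, keeping technical replicates adjacent. Plate coordinates are
  1-based (row A ≡ 1); pixel coordinates are 0-based; the layout module is
  the boundary.
* **Cutoff quantile** uses the linear-interpolation convention (the default
  of mainstream statistics environments): weak densities {4, 8, 12, 16}
  give 7.0. "Greater than" is strict; spots exactly at the cutoff count as
  below. "At least one half" is implemented as 2·n_above ≥ n_spots so odd
  replicate counts (2 of 3) behave sensibly. The reported per-prey density
  averages *all* usable replicate spots, including sub-cutoff ones.
* **Shared-hit percentage** is intersection over union of the two hit sets
  (the published 241/372 = 65% admits no other simple reading). The
  replicate Pearson correlation is computed on raw, zero-filled densities
  over prey positive in at least one replicate.
* **Fold enrichment**: prey enriched for a bait must be positive there with
  mean density ≥ fold × the maximum over other baits; a zero denominator
  counts as enriched. At fold ≥ 2 the per-bait enriched sets are provably
  disjoint when all densities are positive.
* **Hypergeometric enrichment**: upper-tail P(X ≥ k) with the screened
  library as the background universe. The Bonferroni divisor is the number
  of terms annotating at least one hit; terms with no annotated hit report
  p = 1 and do not inflate the correction.
* **Nuclear segmentation**: the "default" automatic threshold is iterative
  intermeans (IsoData). Rolling-ball background subtraction uses the classic
  rolling-ball algorithm (scikit-image), radius in pixels as in the common
  image-analysis tools. Because nuclear-envelope signal is ring-like, holes
  are filled after thresholding (the particle-analysis "include holes"
  behaviour) — without it the 4–12 µm² area window and the circularity
  filter would act on annuli and reject every nucleus. Circularity is
  4π·area/perimeter² with the Crofton (anti-bias) perimeter estimate,
  clamped to 1; circularity cutoffs are convention-sensitive, so the
  convention is part of the contract. Components use 8-connectivity. The
  Gaussian blur sigma is a free parameter, default 2 px. Pixel size must be
  supplied (defaults to 0.1 µm/px, at which the 4–12 µm² window is
  400–1200 px).

## Synthetic data: what it emulates, and what it does not

The generators produce the study conditions every stage is tested under:

* **Test plates**: 384-format lattices (default pitch 24 px) of flat-top
  disc colonies with Gaussian shoulders (pinned colonies are plateau-like).
  Amplitude is scaled so each spot's integrated above-background intensity
  equals its true density exactly before noise — truth is exact, not
  approximate. Per-spot densities are drawn per technical replicate from
  one of four log-normal interaction-strength classes with ordered medians
  (negative 1.5 × 10³, weak 2 × 10⁴, medium 10⁵, strong 4 × 10⁵ on a
  16-bit-like count scale; σ(log) 0.5/0.5/0.4/0.35): colony densities are
  positive and right-skewed, spanning orders of magnitude. A prey is an
  interactor with probability 0.1 (split uniformly across weak/medium/
  strong) — hits are a minority of an arrayed library.
* **Diploid plates**: 96-format flat discs, radius log-normal around 12 px
  (CV 8%); mating failures (rate 0.02) render nothing and zero out the
  prey's test spots.
* **Artifacts**: a smooth low-order polynomial illumination gradient
  (amplitude 10% of the 3000-count background) and additive Gaussian noise
  (σ = 20 counts) — the dominant nuisances of plate photography.
* **Calibration colonies**: labelled density draws with mixture 0.4/0.3/
  0.2/0.1 over negative/weak/medium/strong, emulating the manual
  categorization of ≥ 100 colonies.
* **Nuclear stacks**: 21 planes at 0.3 µm spacing (the 6.3 µm axial range
  is read with an inclusive fencepost — a documented convention, not a
  measured fact), 0.1 µm pixels. Each nucleus is a filled disc of
  nucleoplasmic signal with a brighter envelope ring just inside the rim
  and a steep edge, modulated by a Gaussian axial envelope (σ 0.8 µm); the
  in-plane shape is identical across z, so sum projections preserve it and
  per-nucleus integrated and mean intensities are known exactly. The ring
  is kept ~4 px inside the rim so that a mid-height threshold contour
  recovers the true footprint; truth areas/means are defined on the
  half-maximum footprint. Distractor objects (undersized ~2 µm² and
  oversized ~20 µm² discs, elongated bars of in-range area) exercise the
  area and circularity filters.

All generators are pure functions of (configuration, seed); identical
inputs are bit-identical outputs.

Deliberately not modelled: colony texture and satellite growth, agar and
condensation artifacts, camera nonlinearity and vignetting beyond the
polynomial gradient, plate-edge growth effects, cross-contamination, and —
for stacks — the axial point-spread function, photobleaching and depth
attenuation. Passing recovery tests therefore demonstrates correctness of
the measurement logic under controlled optics, not robustness to every
failure mode of real plate photography or confocal imaging.

## Problem sizes and numerical choices

The standard test screen is 3 library plates (288 prey, 1152 test spots in
quadruplicate) at the default noise and artifact levels, a size at which the
whole pipeline runs in a few seconds while leaving every statistical
property (class separation, dropout handling, cutoff placement) intact; the
nuclear benchmark is a 512×512×21 field of 20 in-range nuclei and 5
distractors. Grid template matching scans 400 pitch candidates × 0.25 px
origin steps per axis. Measurement tolerances established against exact
truth: single-colony density within 5% (7% under a 10% illumination
gradient), disc areas within 10%, per-nucleus mean intensity within 2% at
zero noise, Pearson(measured, true density) ≥ 0.99 at default noise.

Degenerate inputs have defined behaviour throughout: empty value sets are
hard errors; all-equal min–max input maps to 1.0; featureless images yield
empty masks or zero measurements rather than noise-derived artefacts; prey
with no usable spots are emitted as `no_call`.

## Known limitations

* The original screen's plugin did not publish its density formula; this
  implementation's integrated-intensity definition is validated against
  synthetic truth, not against the original tool's outputs.
* One cutoff is calibrated per screen and shared across simultaneously
  screened baits (per-screen recalibration is available by passing separate
  label sets).
* The published replicate correlation (0.88) depends on an unspecified
  transform and prey subset, so it is not a recovery target; raw zero-filled
  densities over union hits are the default here, with log and hits-only
  variants available.
* Enrichment takes term lists as given — no ontology-graph propagation.
* Colony crowding (colonies merging across spots) is not handled; the
  windows assume colonies stay within their cell, which holds for pinned
  arrays at standard densities.
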