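# Methods

This note documents the models and procedures implemented in `acvu`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions.

## The synthetic imaging model

Each animal is a two-channel 3-D stack (default 48 × 48 × 16 voxels,
z-step 260 nm, isotropic voxels by default) containing the four α/β
nuclei of the proximal somatic gonad:

- **Nuclei** are isotropic 3-D Gaussian blobs (σ = radius/2, truncated at
  3σ, renormalised so the noise-free voxel sum equals the nucleus's true
  channel total exactly).  Default radius ≈ 2.5 voxels with per-nucleus
  jitter; centers sit on a laterally jittered 2 × 2 grid with guaranteed
  separation, in the left two-thirds of the frame so a region outside the
  animal always exists for background measurement.
- **The larva mask** is an axis-aligned ellipsoid containing every
  nucleus with margin.  A uniform autofluorescence background (default
  2 AU/voxel) is added inside the mask only.
- **Noise** follows the standard camera model: Poisson shot noise on the
  expected counts plus additive Gaussian read noise (default σ = 80 AU),
  with intensities clipped at zero.  The zero clip makes the effective
  camera mildly compressive for near-zero expected counts — dim regions
  acquire a positive offset that shrinks as local signal grows.  This is
  deliberate: it mimics the noise floor that makes dim VU signals
  genuinely hard to see by eye, which the visibility rule below
  formalises.

**Fluorescence levels.**  GFP::HLH-2 totals are log-normal per fate:
AC median 20,000 AU with log-scale 0.35 (wide enough that, as in real
populations, roughly 85–90% of ACs lie above one SD below the mean);
VU median 2,000 AU with log-scale 0.20 (degraded; 10× dimmer than the
AC).  The mCherry nuclear marker is log-normal (median 30,000, log-scale
0.15) independent of GFP.  A separate *calibration* condition draws every
nucleus's GFP total from one wide log-normal (median 6,300 AU — the
geometric mean of the VU and AC medians — log-scale 0.8) and is used for
parameter-recovery experiments that need the full dynamic range.

**Conditions.**  A `ConditionParams` encodes a genotype or RNAi clone:
the number of AC-fated cells per animal is drawn from `ac_count_dist`
(wild type `{1: 1}`; Notch-null-like conditions put both α cells, and
with some probability β cells, into the AC fate), and
`stabilization_penetrance` is the probability that a VU-fated cell
nonetheless receives an AC-level GFP draw — the phenotype produced by
depleting a GFP::HLH-2 degrader.  The AC always arises from an α cell
unless β cells transform; which α wins when there is one AC is random,
matching the natural variability of the decision.

**What the generator does not emulate:** diffraction and the microscope
PSF, spectral bleed-through, photobleaching, stage drift, anisotropic
blur, nuclear shape irregularity, neighbouring non-gonadal nuclei, and
developmental-stage heterogeneity.  Passing tests therefore demonstrate
that the analysis logic is correct and well calibrated under the stated
statistical structure, not that the segmentation would survive every
real-microscope pathology.

**Reproducibility.**  All randomness flows from one explicit seed through
spawned child generators (`numpy` `SeedSequence`); there is no global RNG
state.  Each sampled animal carries its own render seed, so datasets are
reproducible as a whole and per animal.

## Segmentation

The workflow this pipeline formalises draws nuclear boundaries
interactively on the mCherry histone marker.  The automatic stand-in
here is:

1. Gaussian-smooth the mCherry channel (σ = 1 voxel).
2. Threshold at Otsu's value, floored at median + 6 robust SDs of the
   smoothed image (nuclei occupy < 1% of voxels, where plain Otsu is
   unreliable).
3. Label connected components in 3-D (26-connectivity); drop components
   below 10 voxels.
4. Split components whose volume exceeds 1.8× the median component
   volume by marker-based watershed on the smoothed mCherry; a component
   that resists splitting raises the `merged-nuclei` flag.
5. Redraw each nucleus boundary at its **own isophote**: above-floor
   voxels are partitioned among nuclei by watershed, and each nucleus
   keeps the connected region above 35% of its own smoothed peak.

Step 5 matters.  A single global threshold makes boundary size grow with
marker brightness, and mCherry brightness is independent of GFP — so with
a global boundary the uncorrected background contribution (method B has
no background subtraction) and the integration noise both couple to a
biologically irrelevant variable.  The per-nucleus isophote keeps the
captured fraction of true signal essentially constant across nuclei
(noise-free rank correlation between true and measured totals is ≈ 0.999)
at the cost of capturing a consistent ~70–90% of each total — a
scale factor that cancels in every comparison the pipeline makes, since
all conclusions rest on ranks, thresholds fitted to measured controls, or
within-method contrasts.  35% of peak sits between the half-maximum
(FWHM) convention and the detection floor; it keeps the typical nucleus
spanning ~5–6 z-slices so that method B's five-slice selection remains
meaningful.

Quality control mirrors curation practice, with three exclusion reasons:
`merged-nuclei` (two nuclei segmented as one object), `fragmented-nuclei`
(one nucleus split into several objects), `dim-marker` (marker too weak
to segment).  On synthetic data the ground-truth overlap test is
authoritative; the image-based heuristics cover the no-truth case.
Animals carrying any flag are excluded from screen scoring.

## Quantification

**Method A (`sumproj_bgcorr`).**  Sum z-projection over the slices the
nucleus occupies; GFP integrated intensity inside the planar boundary;
minus the GFP integrated intensity of a region of identical planar shape
placed outside the animal (first raster-order placement that fits),
summed over the same slices.  Subtracting on the projection over the same
slices (rather than per-slice matching) is an interpretation choice and
is documented as such.  Negative corrected values are retained and
flagged — clamping would bias condition means.

**Method B (`top5`).**  Of the slices the nucleus occupies, select the
five with the highest per-slice integrated mCherry; sum the per-slice GFP
integrated intensity inside the boundary over exactly those slices.  No
background correction, as in the screen-quantification protocol this
mirrors; the method is therefore insensitive to dim signals by
construction.  Because the objective is separable and slices are ranked
by an independent key, the rule attains the brute-force optimum over all
5-subsets; ties break toward lower z for determinism.  Nuclei spanning
fewer than five slices use all their slices and are flagged `short-span`
rather than dropped (dropping would bias screens against small nuclei).

Both methods are linear in the GFP channel, and method A is exactly
invariant to adding a uniform intensity to the whole channel.

## Naming, threshold classification, and visibility

Within an animal, the α cell with the higher GFP value is **α₁** (the
presumptive AC), the other is α₂; β₁ is the sister of α₁.  On synthetic
data sisterhood is known; without it, each β is paired to an α by a
one-to-one assignment minimising total centroid distance.  Exact α ties
break toward the smaller centroid x and flag the animal for audit.
Animals with missing or excluded cells get `unknown` roles and are
flagged.

The **AC-like threshold** is fitted on ACs scored in the negative
control: threshold = mean − 1 sample SD (n−1 denominator; control samples
are small).  A cell is AC-like iff its value is *strictly greater* than
the threshold.  Per-role tables exclude the presumptive AC (α₁).

`exclude_top_fraction` removes the ⌈f·n⌉ largest values of a population
before comparison — the correction applied to β-cell populations in
backgrounds where a known fraction of β cells transform to the AC fate.
The ceiling is the conservative rounding; ties break toward the larger
value, and the relative order of retained values is never changed.

**Visible-GFP calls** formalise by-eye scoring: a cell is GFP-positive
iff its measured value exceeds the median of same-shaped, same-slices
background region sums from outside the animal by k dispersions
(k = 5 by default, mimicking a confident visual call; configurable).

## Screen logic

Counts of GFP-positive α/β cells per animal (0–4) feed the hit criteria:

- **negative gate**: ≥ 50% of lacZ-control animals show exactly one
  GFP-positive cell (boundary inclusive);
- **positive gate**: > 50% of lin-12-control animals show more than one
  (boundary strict);
- a round is scoreable only if both gates pass;
- **strict hit**: mean count ≥ 2;
- **lenient hit**: at least one animal with all 4 cells positive and at
  least half the population with > 1;
- clones scored in fewer than 20 animals after QC exclusions are
  unscoreable.

Initial hits are confirmed in triplicate.  The confirmation stringency is
a judgement call not fixed by the criteria themselves; the default is a
majority rule (≥ 2 of 3 replicates meeting strict or lenient), robust to
one failed replicate, with `all` and `any` available.

## Statistics

- **Mann–Whitney U**, two-sided.  Exact mode enumerates the permutation
  distribution of U (valid without ties; the default for pooled n ≤ 12);
  the two-sided exact p doubles the smaller tail and caps at 1.
  Asymptotic mode uses the normal approximation with tie correction and
  continuity correction.  At n = 6 + 6 the exact test's attainable size
  nearest α = 0.05 is 2·19/924 ≈ 0.0411 — the discreteness of U, not an
  implementation artifact.
- **Kruskal–Wallis** with tie-corrected H; chi-square reference with
  k − 1 df, or full enumeration of group-label assignments for pooled
  n ≤ 10.
- **Dunn's post-hoc** z tests on mean ranks vs. a control group, tie
  corrected; the family-wise adjustment is Bonferroni by default (the
  correction convention is a documented parameter, not forced).
- **Fisher's exact 2×2**, two-sided by the probability method (sum of
  hypergeometric probabilities of tables no more probable than the
  observed), computed with exact integer weights so theoretically tied
  tables are never misordered by floating-point rounding.
- **95% CIs on means** are t-based (per-group n in this setting is
  small).

All rank-based p-values are invariant under monotone transformations of
the data.

## Validation battery and problem sizes

`scripts/acceptance.py` (and the mirror tests) recompute, from scratch at
a given seed:

- library arithmetic: 239 conserved-ortholog genes + 1 literature E2 + 7
  ring-between-ring E3s = 247 genes; 232 covered by the 260 available
  feeding clones = 93.9% coverage;
- recovery: Spearman correlation between true and measured GFP totals
  for both methods over 50 calibration animals (200 nuclei), plus the
  uniform-background invariance of method A;
- oracle agreement: slice selection vs. brute-force subsets; exact U
  p-values vs. full labelling enumeration (pooled n ≤ 12); Fisher
  p-values vs. exact-fraction enumeration over all 2×2 tables with every
  margin ≤ 20 (35,650 tables);
- the exhaustive 625-case hit-calling truth table;
- planted-hit recovery over 20 independently seeded screens (10 clones ×
  20 animals, two planted hits at 0.9 penetrance) — sensitivity and
  total false positives;
- the AC-like threshold classifier on a 120-animal negative-control
  population (AC-like VUs, fraction of ACs above threshold, and the
  bright-AC / dim-VU visibility pattern);
- the empirical size of the exact Mann–Whitney test over 10,000 null
  simulations at n = 6 + 6.

These sizes keep the full battery to a few minutes on one CPU while
leaving the stochastic quantities well determined; they are the package's
standard validation conditions.

## Known limitations

- The segmentation stand-in is tuned for the synthetic geometry (four
  well-separated blob-like nuclei); real stacks with touching nuclei,
  heterogeneous marker expression, or neighbouring tissue will need the
  QC thresholds revisited.
- Method B's measured totals include the background under the boundary;
  only comparisons within the same imaging conditions are meaningful.
- The visibility rule is a formal surrogate for by-eye scoring; k = 5 is
  a convention, not an estimate of human performance.
- Arbitrary-unit scales are free parameters: nothing in the pipeline
  depends on absolute intensities, and no camera gain calibration is
  modelled.
- Recovery of rank order degrades for nuclei whose totals approach the
  read-noise floor; at the default acquisition settings the pooled
  true-vs-measured Spearman correlation across the full VU-to-AC dynamic
  range is ≈ 0.95–0.97 depending on the population draw.
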