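# Methods

This note documents the models, numerical choices and limitations behind
`cytoploid`.  It is written for someone who wants to trust (or challenge)
the inference, not for someone learning the API.

## The measurement model

DNA content is proxied by DAPI-stained nuclear area in µm².  This rests on
the empirical monotone relation between nuclear area and DNA amount in
algae where an absolute picogram calibration is unavailable (the
fluorescence intensity of these small nuclei is far below that of the usual
vertebrate standards, so intensities cannot be compared across exposures).
Consequently every quantity in the package is a *relative* genome size;
nothing is reported in picograms.

Within a sample, areas are modeled as a finite mixture on a doubling
series: level k has center `g1 · 2^k` where `g1` is the area of the
unreplicated (G1) population of the lowest ploidy level present.  The G2
(replicated) population of a level coincides with the G1 of the doubled
level, which is what makes endopolyploidy readable from the same
histogram.

### Anchoring: the monoploid unit

Absolute Cx labels require one external anchor.  Gametes are taken as
unreduced (2Cx); the unit is `c = gamete G1 peak / 2`, so a sample with G1
peak at `2c` is diploid-haplophasic, at `3c` triploid-haplophasic, at `4c`
tetraploid-diplophasic.  The 2Cx reading of gametes is a biological
assumption, not something the areas themselves can decide; the
`PloidyAnalyzer` therefore accepts any explicit `unit`, and the anchor
convention can be changed without touching class assignment (assignments
are scale-equivariant: multiplying all areas and the unit by k > 0 changes
nothing).

### Base resolution is a species-level decision

Portions of one thallus (frond, stolon, rhizoid) share the organism's
cytotype, but an individual portion's G1 mean can sit between two
multipliers (e.g. a rhizoid G1 of 0.57 µm² lies nearer 2c = 0.49 than
3c = 0.735 even though the species is triploid).  The pipeline therefore
snaps the base multiplier on the pooled areas of a species/phase group and
passes it to each portion's fit (`PloidyAnalyzer(base_multiplier=...)`).
Snapping is nearest-in-log2 over the allowed multipliers
{2, 3, 4, 6, 8, 12, 16, 32}, accepted within `max_log2_offset = 0.30`
(slightly more than half the widest inter-multiplier gap, so any ratio
inside the series range resolves to its nearest level); ratios outside the
band — e.g. below ~1.6 — raise an unresolved-cytotype error rather than
guessing.

## Reading the histogram

* **Binning**: fixed width 0.1 µm², half-open bins, lightly smoothed with
  a 3-bin moving average before peak picking.  0.1 µm² resolves the
  0.5 / 0.7 / 1.0 separation at gamete scale without fragmenting modes at
  realistic n.
* **G1 peak**: the maximal smoothed mode; ties across separated modes
  resolve to the smaller area with a warning (most interphase time is
  spent in G1), a flat histogram raises an ambiguity error.  The sub-bin
  position is refined by an iterated symmetric local mean: a window of
  half-width 0.3·peak whose center tracks the running mean.  The additive
  (not multiplicative) window matters — a multiplicatively symmetric
  window is wider above than below the center and drags estimates upward
  for broad classes.
* **Class boundaries**: geometric means of adjacent centers, i.e. the
  log-space midpoint, the unique choice consistent with a multiplicative
  class structure (for centers 0.5 and 1.0 the split falls at 0.707, the
  0.70/0.71 split conventionally used for gametes).  Outer bounds
  extrapolate the geometric ratio; records beyond them are assigned to the
  nearest class and flagged `out_of_series`.
* **Overlap half-split**: records within a multiplicative band of ±10%
  around a shared boundary are pooled, sorted, and the lower ⌊n/2⌋
  assigned to the lower class, the rest to the upper, flagged
  `overlap_split_*`.  This reproduces the manual curation convention for
  overlapping somatic levels; the band width is configurable
  (`overlap_frac`).

### Which classes are occupied

With heavily dispersed classes (CVs up to 0.35), the upper tail of one
class spills across the boundary into the next, so "count > 0" is not
evidence that a level exists.  A candidate class above the base is accepted
iff either

1. its member count exceeds the expected spill-over from the nearest
   accepted class below by 3 Poisson sigmas, where the spill estimate uses
   the donor's mode-seeded center and a robust *upper-sided* scale
   (q90 − median, normalized); the upper-sided quantile is used because the
   donor's own interval is contaminated on its low side by the class below
   it; or
2. the smoothed histogram has a mode of at least two nuclei within ±20%
   of the class center.

Rejected classes are merged downward with flag `pruned_merged`.  This is
the package's operationalization of "reading the histogram by eye"; it is
deliberately not a mixture-model fit — the procedure being reproduced is
boundary-based, and a likelihood fit would change what is being tested.

Class-center estimates (used for reporting and recovery checks) come from a
one-shot symmetric window (half-width 0.2·center) seeded at the class's own
histogram mode when one exists; classes with fewer than 5 nuclei use the
plain member mean, which is less biased than any window anchored on the
doubling grid.

### Phases and endopolyploidy

The lowest occupied class is G1 of the base level; a class at twice an
occupied class is its G2 and, where the chain continues, simultaneously
the G1 of the doubled level.  Records are labelled G1 / G2 / endo
accordingly.  A sample is flagged endopolyploid when more than two size
classes occur in somatic (non-gamete) tissue.

## Synthetic data

No raw per-nucleus measurements are deposited for this system, so the
generator regenerates populations with the documented statistical
structure: per class, a normal truncated at zero with the published class
mean and SD (CVs 8–35%), independent across nuclei.  The ten presets carry
the published per-portion class means, SDs and exact per-class counts; a
single-nucleus class (with no printable SD) uses a default CV of 0.10.
Presets sample with *exact* per-class counts rather than multinomially:
several published classes contain 1–3 nuclei, and multinomial resampling
would delete them from the generating truth in a third of the draws,
making recovery meaningless.  Weight-specified `SyntheticSpec`s without
counts sample multinomially.

What the generator does *not* emulate: within-individual correlation of
nuclear sizes, measurement error separate from biological variance (the
published SDs fold both together, and so does the generator's CV),
non-normal class shapes, and any spatial structure of the thallus.
Passing recovery tests therefore show that the inference chain is
self-consistent under the study's own summary statistics — not that it
would survive, say, heavy-tailed measurement error.

### Field rendering

Fields are rendered at 0.1 µm/pixel (so the smallest 0.6 µm nuclei span
6 pixels) on a background of 80 camera units with additive Gaussian noise
(σ = 40): nuclei as homogeneously filled anti-aliased disks at ~1200 units
(±15% per-object jitter) whose analytic area is the ground truth;
chloroplasts 5–7 µm across with a bright 2.5-px rim and dim core;
bacteria 0.25–0.5 µm bright dots.  Objects are placed by rejection
sampling with no overlap and a border margin.  Ground-truth areas are
analytic (πr²), not mask pixel counts, so the calibration test is
independent of rasterization.

## Image quantification

Detection: Gaussian pre-smoothing (σ = 1 px), global threshold at
median + 6·MAD-sigmas, small-object and border-object removal, watershed
splitting only for candidates with solidity < 0.92 (clean disks are never
split).  Each candidate is then re-segmented at the half-maximum level —
the peak is read from the smoothed image but the contour is cut on the raw
image, because smoothing contracts the half-max contour of small convex
objects and biases areas low.  Holes (dim plastid cores) are filled before
measuring.  Calibrated area is pixel count × pixel_scale²; remaining area
error is pixel-center rasterization of the disk boundary, ~2% at the
default scale.

Classification uses three morphological features, applied in order:
equivalent diameter below 0.6 µm → bacterium; 2-px-rim / eroded-interior
intensity ratio above 1.5 → chloroplast; diameter within 0.6–4 µm with
interior homogeneity `1 − sd/mean ≥ 0.5` and no rim excess → nucleus;
otherwise unclassified.  Bacteria are distinguished by size alone — the
camera model is single-channel, so spectral autofluorescence is not
represented.  All thresholds are parameters of `ClassifierThresholds` and
CLI flags.  The pixel calibration is always user-supplied; nothing in an
image fixes its own scale.

## Statistics

Group summaries are n / mean / SD (denominator n−1).  One-way ANOVA is the
classical fixed-effects decomposition with p from the F distribution;
`anova_from_components` completes a published table (MS, F, p) from its
printed SS/df, which is how the reproduction script re-derives the printed
F ratios.  The two-sample t-test is pooled Student by default — the
published degrees of freedom all equal n₁+n₂−2, which identifies the
pooled form — with Welch available by flag.  Significance convention is a
conservative α = 0.001.  p-values are floored at machine tiny rather than
printed as exact zeros.  "Minimum genome size" comparisons use the G1
subset (lowest occupied class); "first level" adds its 2× G2 class.

## Problem sizes and reproducibility

Every stochastic experiment flows from one root seed through
`numpy.random.SeedSequence` spawning.  The recovery benchmark regenerates
all ten presets at their published sizes (3 156 nuclei per replicate) for
15 replicates, reporting majority outcomes for discrete quantities and
replicate means for class centers — chosen because classes of 1–9 nuclei
make single-draw point estimates noisy by construction (a 3-nucleus class
with SD 1.29 µm² has a ±0.74 µm² standard error in any single draw).  The
detection benchmark scores 20 rendered 512×512 fields (12 nuclei,
2 chloroplasts, 6 bacteria each).  Both run in a few seconds.

## Known limitations

* The unit anchor inherits the sampling noise of 26 gametes (±4%); a
  species whose G1/unit ratio falls near the midpoint of the 2–3 gap can
  occasionally snap to the wrong base in a single replicate.  The pooled
  species-level fit plus replicate majority makes this negligible in
  practice, but single-sample, single-seed base calls near ratio ~2.45
  should be treated as unresolved.
* Class presence detection is a heuristic stand-in for by-eye histogram
  reading.  Its two failure modes are symmetric: a 1–2-nucleus true class
  adjacent to a broad lower class can be pruned as spill, and a heavy
  upper tail can occasionally mint a phantom class.  Both occur in ~5% of
  single-sample draws at the published sample sizes.
* Classification of plastids relies on the rim/core contrast; densely
  packed or out-of-focus plastids in real micrographs will not look like
  the rendered ones, and thresholds will need re-tuning against annotated
  real fields.
* No mixture-likelihood fitting, no chromosome counts, no picogram
  calibration, no 3-D stacks, no multi-channel unmixing.
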