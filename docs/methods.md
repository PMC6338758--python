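# Methods

This note documents the models, conventions and numerical choices behind
`flycourt`, and what the synthetic-data tests do and do not demonstrate
about real assay data.

## Angle measurement and classification

The deviation angle of the male genitalia is the signed angle between the
abdominal midline direction (anterior → posterior) and the genitalia axis
(anus → penis, the penis taken as the middle of the claspers).  It is
computed as `atan2(cross, dot)` of the two direction vectors in double
precision and wrapped to (−180°, 180°]; positive = deviation toward the
fly's right as seen from the posterior end.  Because only the two directions
enter, the measure is invariant under translation, rotation and uniform
scaling of the landmark coordinates — verified by property tests over random
similarity transforms.  Coordinates are in the image frame (y increases
downward), the frame in which genitalia photographs are annotated.

The eight classes partition the circle with bins anchored at the printed
endpoints 22°, 67°, 112°, 157°: the 0° class is the open interval
(−22°, 22°), each lateral bin is half-open with the shared endpoint assigned
to the class farther from 0° (so Right 22° is already Right 45° class), and
the 180° class absorbs both approaches, [157°, 180°] ∪ (−180°, −157°].  The
resulting widths are 44° (0°), 46° (180°) and 45° for the six lateral
classes; forcing equal 45° bins would move the printed endpoints, so the
slight asymmetry is kept deliberately.

Rotation arithmetic: for a counterclockwise developmental rotation, a final
deviation of Left *d* corresponds to a rotation of *d* degrees and Right *d*
to 360 − *d*; clockwise is the mirror.  The 0° class is exposed as the
two-valued set {0°, 360°} — the final anatomy cannot distinguish "never
rotated" from full circumversion, and both occur in *Myo31DF* mutants — so
`rotation_difference` refuses the 0° class rather than guessing.

## Copulation detection

The detector follows the merged-silhouette principle: while the male mounts
the female the two dark body outlines form a single connected region.

- **Sampling**: one frame every 10 s starting at t = 0 (configurable).
- **Binarization**: per-frame Otsu threshold on the grayscale image, dark
  foreground (`value ≤ threshold`).  With well-separated intensity modes the
  between-class variance is flat across the empty gap and the implementation
  returns the lowest maximizing bin, so the threshold sits directly above
  the fly mode; including the threshold value itself in the foreground is
  what makes recovery of noise-free shapes exact.  A fixed threshold can be
  supplied instead.
- **Components**: 8-connected, so silhouettes touching at a pixel corner
  merge; components below 25% of the expected single-fly area are discarded
  as specks.
- **Merge criterion**: a sample is *merged* when exactly one fly-sized
  component remains **and** its area is ≥ 1.4 × the single-fly reference
  area (the mounted pair overlaps ~60%, giving ~1.4×; two merely touching
  flies give ~2×, also above).  The reference area is the median of the two
  largest component areas over clearly-two-fly samples, falling back to half
  the largest component if no such sample exists.  The dual test protects
  against a single fly plus a lost fly being read as a merge.
- **Calling**: maximal runs of consecutive merged samples become copulation
  intervals.  "More than one minute" is strict; the span of a run is its
  occupancy span, last sample − first sample + sampling interval, so at 10-s
  sampling a 7-sample run spans 70 s and passes while 6 samples (60 s)
  fail.  No gap is tolerated by default ("continuously"); an
  `allow_gap_samples` option exists.  A run still merged at the final sample
  is emitted with a truncated flag whatever its span — the mount may be
  ongoing and the recording should be extended — but only spans strictly
  above the rule count as success.

The space–time volume is simply the stack of binarized samples with
timestamps, written as a 1-bit-per-pixel multi-page TIFF; `lookup(t)` is the
digital analogue of scrubbing a synchronized time bar across the stack.

## Behavioral metrics

Courtship latency is the start of the earliest wing-vibration event; males
that do not initiate within the 600-s window are excluded, and the exclusion
reason is recorded per assay.  The courtship index is the union length of
the six courtship-component intervals (orientation, tapping, following,
wing vibration, licking, attempted copulation) clipped to the first 600 s,
divided by the window — the union reproduces what a stopwatch running during
"any courtship activity" measures, keeps overlapping components from
double-counting, and bounds the CI at 100.  Copulation itself is not a
courtship component and never enters the CI numerator.  One wording
ambiguity had to be resolved: the CI exclusion is applied on failure to
*initiate courtship* within 10 minutes, the same rule as the latency
exclusion, rather than on failure to copulate — the latter reading would
discard nearly every unsuccessful male and make the CI comparison vacuous.

Success rates are reported per stratum (angle class × female genotype ×
mating duration) with exact counts and a 3-significant-figure percentage
rendering (66.2, 7.14, 1.96, 100, 0).

## Statistics

- **Fisher's exact test**, two-sided by the point-probability rule: p is the
  sum of all hypergeometric point probabilities not exceeding the observed
  table's.  This is the convention of R's `fisher.test`; the central
  (doubled one-tail) convention is available behind a flag.  The test suite
  checks the implementation against full integer-weight hypergeometric
  enumeration on every 2×2 table with N ≤ 40.
- **Kruskal–Wallis** with tie correction, chi-square reference with k − 1
  df.  Null p-values are checked for approximate uniformity by simulation.
- **Steel–Dwass** all-pairs comparisons, written in-house (no implementation
  exists in the dependency stack): each pair is ranked jointly, the rank sum
  standardized with the tie-corrected variance, and √2·|z| referred to the
  studentized-range distribution with (k, ∞) parameters.  An exact
  permutation option exists for tiny samples.  Simulated family-wise error
  at k = 4, n = 10/group is ≈ 0.05.
- **One-way ANOVA + Tukey HSD** (Tukey–Kramer for unequal n), delegated to
  scipy; the F = t² identity for k = 2 and a hand-computed balanced fixture
  pin the wiring.
- Significance at α = 0.05 throughout.  Separate planned contrasts are not
  multiplicity-adjusted across tests (only Steel–Dwass/Tukey adjust within
  their own families), matching common practice for planned comparisons.

## Synthetic assay generator

The generator emulates the recorded assay: a circular chamber 8 mm in
diameter and 3 mm high, one virgin female and one male, one hour of
observation.  Defaults:

| parameter | default | rationale |
|---|---|---|
| arena diameter | 8 mm | chamber geometry of the assay |
| fly body | 2.5 × 1.0 mm ellipse | typical adult *D. melanogaster* body size; not reported in the assay description, configurable |
| resolution | 10 px/mm | enough that a fly spans ~25 px and Otsu is stable; configurable |
| frame interval | 1 s | finer than the 10-s analysis cadence, so sampling is genuinely exercised |
| duration | 3600 s | the one-hour assay |
| grayscale levels | background 200, fly 40 | dark flies on a light arena |
| pixel noise σ | 6 | Otsu recovers ≥ 99% of true fly pixels at this level (verified by test) |

The male runs a semi-Markov behavioral state machine (idle → orientation →
tapping → following → wing vibration → licking → attempted copulation →
copulation) with exponential dwell times; a mounting attempt leads to
copulation with configurable probability, at most once per assay (after a
completed copulation the male stays quiescent, matching the observation that
pairs copulate only once in the hour).  A `scripted_events` list overrides
the sampler entirely, giving detector tests exact ground truth.  The emitted
event log *is* the state machine's trajectory; a copulation still running at
the nominal end carries a truncated flag.

Movement is a bounded random walk; during courtship the male pursues the
female at a standoff, and during copulation the male ellipse is clamped onto
the female's posterior at a 0.4-body-length offset (~60% area overlap),
guaranteeing a single connected component.  Outside copulation a separation
floor — always achievable inside the walking disk and larger than one body
length — keeps the silhouettes disjoint, so merged frames coincide with
scripted copulation intervals to within one frame interval.  Two
confinement radii are used: free-walking flies keep 0.55 body lengths of
clearance from the wall, a mounted pair 0.9, so every rendered pixel stays
inside the arena disk.

Determinism: the behavioral/motion stream and the pixel-noise stream are
independent children of `SeedSequence(seed)`, so identical (config, seed)
gives bit-identical frames and logs, and the noise-free twin of a noisy
simulation has identical geometry (this is how ground-truth masks are
obtained in tests).

Outcome tables draw one record per simulated male: copulation ~
Bernoulli(p_cop), offspring ~ Bernoulli(p_off / p_cop) conditional on
copulation, so the offspring marginal equals the requested class probability
while offspring-without-copulation is structurally impossible (as observed:
males that failed to copulate never sired offspring).  The default per-class
offspring probabilities are the reported 4-day-mating reproduction rates for
wild-type females (66.2, 33.9, 1.96, 3.18, 0, 0, 3.03, 46.2% around the
circle) and *Myo31DF* homozygous females (75.0, 60.0, 9.80, 0, 0, 0, 0,
65.0%).

**What the generator does not emulate**: wings and legs (the detector is
deliberately insensitive to sub-copulation courtship structure), lighting
gradients and shadows, reflections at the chamber wall, partial occlusion at
the wall, fly-size variation, and female rejection behavior.  Passing the
detector suite therefore shows that the sampling/binarization/merge-run
logic is correct on well-segmented silhouettes, not that segmentation is
robust to arbitrary real-world video; on real footage the fixed-threshold
option and the merge factor are the knobs to adjust.

## Pipeline determinism and problem sizes

The pipeline fans the global seed out through
`SeedSequence(seed, spawn_key=(stage, index))`, so any stage can be rerun in
isolation.  Reports are serialized with sorted keys and floats rounded to
9 decimals, making reruns byte-identical.

Test and acceptance runs use scaled problem sizes chosen to keep the suite
quick while leaving every mechanism exercised: 600-s assays rendered at 5-s
intervals (still finer than the 10-s sampling) for the 50-assay detector
suite, 1500 replicates for the Steel–Dwass family-wise-error simulation,
5000 for Kruskal–Wallis null uniformity, 100 outcome-table replicates at
n = 60/class for parameter recovery.

## Known limitations

- The merge criterion is a proxy: the original analysis confirmed merges by
  eye from the video, and the exact adjudication rule for borderline frames
  is unknowable; the area × component-count test is our operationalization.
- A 0°-class male's rotation amount is irreducibly two-valued ({0°, 360°});
  any statistic over rotation amounts must exclude or specially handle that
  class.
- Fly identity is not tracked; the detector cannot say which fly is which,
  only whether the pair is merged.
- The latency/CI group comparisons in the bundled pipeline run on simulated
  assays whose latency distributions are identical across groups by
  construction; they demonstrate the statistical plumbing, not a biological
  effect.
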