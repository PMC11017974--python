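# Methods

## Scope and units

The unit of analysis is the *colony*: all clonal rediae dissected from one
infected snail. All lengths are micrometres (μm), volumes cubic
micrometres (μm³); files carry these units verbatim with no
auto-detection. Missing measurements are empty CSV cells, never 0 or −1,
and records flagged unreliable are loaded with `excluded=True` (with a
reason) rather than dropped, so row counts are conserved.

## Morphometric model

A redia is treated as a cylinder: body volume V = π(w/2)²L from midline
length L and widest width w (excluding protrusions). The pharynx is
treated as a sphere of the measured diameter d: v = (4/3)π(d/2)³. The key
caste morphometric is the relative pharynx volume v/V, which is invariant
under isometric growth and rises in smaller rediae whenever pharynx size
scales with a length exponent below 3 on volume (equivalently below 1 on
length). Standard linear size SLS = V^(1/3) linearises volume for display.
No shrinkage or movement correction is applied to live-photo measurements:
measurement noise from body flexing is small relative to the size
differences the battery tests. Ratios v/V > 1 are geometrically impossible
and are flagged on the record but not silently removed.

## Size-caste designation

Two branches, chosen per colony:

1. **Histogram trough.** If a Shapiro–Wilk test on ln V rejects normality
   (α = 0.05), the log10 V histogram is built with the class count of
   Sturges' rule, ⌈log₂ n⌉ + 1, and breakpoints snapped to "nice" numbers
   (1, 2 or 5 × a power of ten, using the same unit-selection biases as
   R's `pretty()`), i.e. the default histogram of the R environment in
   which this kind of field data is conventionally analysed. Bins are
   right-closed with the lowest bin closed on both ends. If the two
   highest local-maximum bins (plateaus collapsed leftward) each hold at
   least `min_peak_count` observations and the emptiest bin strictly
   between them holds at most `trough_ratio` times the smaller peak, the
   colony is called bimodal and every redia at or below the trough-bin
   midpoint (back-transformed) is small, the rest large. Tied trough bins
   resolve toward the midpoint of the peaks, then to the lower index.
2. **Quartile fallback.** Otherwise the smallest 25% of volumes are
   compared with the largest 25% (type-7 interpolated quantiles, index
   (n−1)p+1, boundaries inclusive), the middle half being intermediates.
   This mirrors the fallback used when a colony shows no clear size gap.

A `manual_override` path accepts a user-supplied cutoff per colony.

### Calibration of the trough rule

The trough rule replaces a visual "two distinct peaks" judgement, so its
two free parameters were calibrated by simulation *before* the test suite
was frozen. With defaults `min_peak_count = 3`, `trough_ratio = 0.75`, the
rule calls 14–25% of genuinely unimodal lognormal colonies bimodal at
n ≈ 100–120 — far noisier than a human reader. The shipped defaults
`min_peak_count = 5`, `trough_ratio = 0.6` hold the false-positive rate at
~2–5% while detecting widely separated mixtures (≥ 5 mode-SD apart, the
marine soldier pattern) essentially always.

A hard limit worth stating: with Sturges binning the bin width is roughly
1–1.4 mode-SD at realistic n, while an equal two-component normal mixture
whose modes are 3 SD apart has a density trough only ~36% below its peaks
(and at mixing weight 0.2 the density has *no* local minimum at all). No
setting of the rule detects such marginal mixtures at ≥ 90% sensitivity
without breaking the false-positive bound; measured sensitivity at exactly
3 SD separation is ~30–35%. Bimodality calls should therefore be read as
"clearly two-peaked", not as a mixture test; caste *labels* remain
accurate (≥ 95% agreement with the generating component at 3 SD, because
the quartile fallback classifies only the confident tails).

## The pattern battery

All tests use α = 0.05 with **no multiple-testing correction** — with
eight patterns per colony, about 5% of significant calls are expected
false positives, and the output stores every p-value so readers can apply
their own correction. Significance is strict (p < α).

- **Volume**: Y = bimodal, N\* = non-normal but not bimodal, N = consistent
  with lognormal volumes.
- **Reproduction**: maximum embryo presence score (ordinal 0–4: definitely
  absent … definitely present) over the five smallest rediae; 4 → Y,
  3 → Y?, 2 → U, ≤ 1 → N. N (embryo-free small rediae) is the
  DOL-consistent outcome.
- **Morphology**: one-tailed rank-sum (smallest five > largest five) on
  anterior and posterior appendage scores separately; Y if both
  significant, O if one, N if neither.
- **Pharynx**: one-tailed rank-sum on relative pharynx volume
  (small > large); a companion test on absolute pharynx volume
  (large > small) is stored as `abs_pharynx`. NA when a size class has no
  usable pharynx measurement.
- **%Small**: 100·n_small/(n_small+n_large), reported only for colonies
  with a bimodal volume call (NA otherwise), because the quantity is not
  meaningful when the small/large split is an arbitrary quartile cut.
- **Distribution**: per snail section (apical = gonad/digestive, mid,
  head/foot), the proportion of classified rediae that are small, with
  exact Clopper–Pearson 95% CIs; the anterior section is the head/foot, or
  the mid section when the foot holds no classified rediae. Y = anterior
  proportion higher with disjoint intervals, O = overlap, N = reversed
  with disjoint intervals, NA = sections unavailable. The CI method is
  recorded in the output so an alternative (e.g. Wilson) can be swapped.
- **Activity**: per redia, the 2-s distances at 0 and 15 min are averaged
  (a single timepoint is used as-is) and divided by body length; small vs
  large compared two-tailed, with the direction reported (the DOL
  prediction — small more active — is noted in the result). Absolute
  distance is reported as a companion statistic.
- **Attacks**: total observed attacks by small vs large rediae across
  wells; Y only if small attacks outnumber large. Counts only — no
  per-capita rate model.
- **Large pharynx**: Tukey screen on pharynx *diameter* (configurable to
  volume; the two are not equivalent because fences are not invariant
  under the cubic transform): outliers are values strictly above
  Q3 + 1.5·IQR; a colony is flagged as containing a large-pharynx
  subpopulation when the outlier fraction is ≥ 5% (inclusive), matching
  the 5–15% range reported for colonies with visually obvious
  large-pharynx rediae.
- **Growth trend** (culture data): OLS slope of mean redia length on day,
  two-sided t-test, requiring ≥ 3 timepoints.

Behavioural patterns (Activity, Attacks) are computed only for
saline-dissected colonies by default: osmotic stress suppresses movement
in water-dissected rediae, making media incomparable. An
`include_water_behavior` override exists.

### Rank-sum test

Mann–Whitney U on midranks. For combined samples ≤ 12 the p-value is
computed by enumerating all C(n, n₁) assignments of the pooled
observations (exact conditionally on the observed values, hence valid
under ties; the `exact` flag is set only for tie-free data). Larger
samples use the normal approximation with tie-corrected variance and a
0.5 continuity correction, matching the classical corrected test (verified
against R's `wilcox.test` to 10⁻⁹). Two-sided p-values double the smaller
tail, capped at 1. Measured type-I error of the one-tailed test at
n = 25/25 over 10,000 replicates is ~0.048–0.050.

## COI species delimitation

Percent identity between aligned sequences counts only columns where
neither sequence has a gap or N. Unaligned input goes through a built-in
Needleman–Wunsch global aligner (match +1, mismatch −1, gap −1; traceback
ties prefer substitution, then a gap in the second sequence, then the
first), verified against brute-force enumeration on short sequences;
already-aligned FASTA bypasses it. Species are single-linkage connected
components over pairs with PI ≥ 95% (inclusive boundary): any qualifying
similarity merges, which also keeps chains (A–B 96%, B–C 96%, A–C 92%)
together as one species. Cluster labels and representatives are the
lexicographically smallest member id, making output order-invariant. The
exact identity convention of other aligners may differ near the 95%
boundary; the convention is recorded in the output metadata.

## Synthetic colony generator

`simulate_colony` emulates the data structures the battery consumes, with
every draw flowing from one integer seed:

- **Volumes**: log10 V from a two-component normal mixture. Defaults:
  modes (6.0, 6.45), SD 0.15, small fraction 0.5, n = 120. These describe
  a moderately bimodal freshwater-like colony — a 2.8-fold volume gap
  (3 SD on the log scale), nothing like the 10s–100s-fold gaps of marine
  soldier-producing species — at roughly the per-colony sample size of a
  field survey (~100–300 measured rediae, the sampling target being 100
  per snail section).
- **Shape**: width tied to length by a fixed aspect ratio (default 4), so
  L = (4·a²·V/π)^(1/3) inverts the cylinder formula exactly.
- **Pharynx allometry**: d = 0.43·L^b·exp(ε), ε ~ N(0, 0.1) on the natural
  log scale; b = 0.75 (negative allometry, the signal the Pharynx test
  detects) by default, b = 1 for the isometric null. 10% of pharynges are
  unmeasured at random, mimicking pharynges not visible in photos.
- **Large-pharynx subpopulation**: a configurable fraction of *all* rediae
  (drawn from the large caste, default multiplier 2× diameter).
- **Sections**: caste-dependent multinomial over apical/mid/foot.
- **Presence scores**: latent score 4·(structure present) + logistic noise
  (scale 0.5), rounded and clamped to 0–4 — the simplest ordinal-blur
  model with one tunable width.
- **Activity**: lognormal 2-s distances with caste-specific median scales
  (5 and 7.5 μm in water) and a ×2.5 saline multiplier, two timepoints per
  redia; body lengths drawn from the caste's volume component.
- **Attacks**: one well per caste × target type (colony mate, conspecific,
  heterospecific), 10 rediae per well, Bernoulli attack counts.

`simulate_coi` draws one ancestor, mutates species founders from it at the
given per-site rate, and mutates members from founders at a rate
calibrated so the expected *pairwise* divergence between two members of
one species equals the within-species parameter (for small q, roughly
q/2 per member). Typical observed divergence between members of different
species is therefore about twice the between parameter — deliberately far
from the 95% clustering threshold, so species recovery measures the
clustering logic rather than threshold luck. Substitutions are uniform
over the three alternative bases; there is no transition bias, codon
structure or rate heterogeneity, none of which matter for threshold
clustering.

What the generator does *not* emulate: measurement-software calibration
offsets between observers, non-cylindrical body shapes, within-colony
spatial autocorrelation of sizes, redia age structure, or sequencing
error. Passing recovery tests therefore demonstrates that the battery's
logic is correct under its own modelling assumptions, not that those
assumptions hold for any particular field dataset.

`make_benchmark_suite` emits three archetypes × 10 replicates with a
ground-truth manifest: `dol_like` (wide 6-SD bimodality, embryo-free
small caste with strong appendages and b = 0.6 allometry, foot-biased),
`freshwater_like` (the defaults plus a 10% large-pharynx subpopulation),
and `null` (no caste structure, isometric pharynges).

## Validation experiment sizes

`scripts/acceptance.py` and the acceptance tests use: all two-group
partitions of n ≤ 8 for exact-test oracle agreement; 10,000 replicates for
rank-sum type-I error; 200 colonies × 100 rediae for pharynx power and
caste agreement; 1,000 colonies for the isometric null rate (sized so the
Monte-Carlo error is small against the ±2% band); 200 colonies × 300
rediae for bimodality detection rates; 100 colonies for large-pharynx
recovery; and 100 runs of 20 species × 3 sequences × 600 bp for species
recovery. On one CPU the whole script runs in under a minute.

## Known limitations

- The histogram-trough rule is a coarse instrument (see calibration note):
  it is faithful to default-binned visual inspection, not a mixture model
  or dip test, and misses marginal (≈ 3 SD) bimodality most of the time.
- The Distribution pattern's "disjoint 95% CIs" criterion is conservative
  relative to a two-proportion test.
- Attack data are bare counts; with few trials the Y/N code carries little
  evidence either way.
- The aggregate report's per-species count strings always reflect true
  column sums over the included colonies.
- Percent-identity values near the 95% species boundary can differ between
  alignment conventions; borderline pairs deserve inspection.
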