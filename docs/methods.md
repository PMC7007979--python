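# Methods

This note documents the models, conventions and numerical choices behind
`lionwelfare`, in the spirit of a statistical package's methods appendix.

## Observation model

The unit of observation is the instantaneous scan: once per minute within
a one-hour session, the observer records the subject's behaviour and its
enclosure zone.  Sessions fall in three time blocks (0500–1100,
1300–1800, 2200–0500).  Scan tables may contain any ethogram behaviour —
states, discrete ("event") behaviours, or stereotypies — because the
instantaneous record is whatever the animal was doing at the minute mark;
separately tallied all-occurrence event counts can additionally be
attached to sessions and are pooled into the diversity index on request.
Missing minutes within a session are permitted (observer gaps); N is
always the count of recorded scans, never the nominal 60.

The default ethogram has 5 states, 14 events and 4 stereotypy categories
(pacing, swaying, head bobbing, nose rubbing).  Zones are categorical
tokens with area fractions, not geometry; the default map divides each
enclosure into ten equal zones, and unequal fractions are supported
because the SPI's f_e,min correction only matters when zones differ.

## Index conventions

* **SPI** = Σ|f_o − f_e| / (2(N − f_e,min)).  Undefined for N = 0 or
  N ≤ f_e,min.  On equal-area maps it lies in [0, 1], is 0 for perfectly
  uniform counts and 1 for single-zone confinement, and is invariant to
  scaling all counts by a positive integer.
* **SWI** uses the natural logarithm (nats), the convention under which
  per-subject diversities of a ~19-behaviour felid repertoire fall in the
  observed 0.7–1.3 range.  Zero-count behaviours are ignored.  The
  headline value pools each subject's observations across all sessions;
  a per-session variant is exposed for diagnostics.  Stereotypies are
  excluded (they are not species-typical); a states-only mode exists.
* **ARB bouts**: "persisting over five consecutive scans" is read
  boundary-inclusive (length ≥ 5; configurable).  Runs require
  consecutive recorded minutes within one session — gaps are never
  bridged and bouts never span sessions.  A scan carrying any exclusion
  context flag cannot belong to a bout (it has an observer-discernible
  cause), so a flagged scan splits a run; each fragment qualifies on its
  own length.  ARB% = 100 × (scans in qualifying bouts) / (all scans).
  Removing a flag can only merge or extend runs, so ARB% is monotone
  non-decreasing under flag removal.
* **Latency**: trials are censored at the 600 s test length (latency set
  to 600, censored flag raised); failure to approach within 300 s flags
  the trial behaviourally shy but never discards data.  A subject's
  latency is the mean over its repeated novel-object trials; the
  censored flag propagates if any contributing trial was censored.

## Personality

Ratings (1–9, three raters, ten bold + ten shy traits) are averaged over
raters per trait, then over each trait class.  The label rule is strict:
bold iff mean bold > 7 and mean shy ≤ 7, mirrored for shy; dual- or
no-qualification yields "unclassified" rather than a forced label, since
ties have no documented treatment.  Cronbach's alpha treats raters as
items and subject × trait pairs as rows (the layout that directly asks
"do raters order the ratings the same way"); a per-trait alpha report is
also available.  Keeper labels are validated — never overridden — by the
novel-object results, and subjects whose repeat sessions disagree on the
behavioural bold/shy categorisation are excluded from the group
statistics *after* index computation, mirroring the field workflow.

## Statistical layer

* Two-group contrasts for SPI, SWI and ARB% use the pooled-variance
  Student t with df = n₁ + n₂ − 2 (df = 33 at the default 16/19 and
  21/14 splits); the Welch form is available via `equal_var=False`.
  Published tables in this literature mix the two conventions, so both
  are first-class.
* Latency contrasts use the two-sample Kolmogorov–Smirnov test, reported
  as z = D·√(n₁n₂/(n₁+n₂)) with the asymptotic (Kolmogorov) two-sided
  p-value, the form commonly printed as "KS z".
* Effect sizes default to Cohen's d with the root-mean-square-of-SDs
  denominator √((s₁²+s₂²)/2).  This average-SD standardiser reproduces
  published effect sizes in this literature where the pooled-SD variant
  (also provided) does not, because it does not weight by group size.
  Statistics are reported as magnitudes with an explicit direction
  field, avoiding sign-convention ambiguity.
* p-values are two-sided and uncorrected by default (a Holm-adjusted
  column is optional), matching standard reporting in the field.
* The diversity regression is OLS of SWI on SPI and ARB% with standard
  errors, F, R², Durbin–Watson on residuals in roster order, and VIFs
  computed on the design before fitting (VIF > 10 warns).
* Shapiro–Wilk and Levene screening is advisory; latency is routed to
  the KS test unconditionally, as is conventional for right-skewed
  approach latencies.
* Constant columns in the correlation matrix are flagged as degenerate
  (r = NaN), never silently zero.  A factor level with fewer than two
  subjects skips that comparison with a warning.

## Synthetic-study generator

The generator emulates the study conditions end to end so that the
pipeline can be exercised, and its estimators validated, with known
ground truth.

**Composition.** The default roster is the 35-subject study population
(21 bold / 14 shy; 16 captive-raised / 19 wild-rescued; 14 M / 21 F;
17 pair- / 18 group-housed; enclosure sizes 1,100–6,542 m², ages in
days).  Any factorial composition can be supplied instead.

**Targets.** Per-group index targets default to the published group
summaries (mean ± SD of SPI, SWI, ARB% and latency by personality and by
origin).  Personality × origin cell targets are solved from those
marginal summaries at run time: the four margin equations are rank-3 and
(because the inputs are printed to two decimals) slightly inconsistent,
so the solver takes a minimum-norm least-squares correction to an
additive prior (cell = mean of its two margins), reproducing each margin
to within a few percent of its SD.  Cell variances are solved the same
way after removing between-cell mean spread, floored at (0.3 × smallest
marginal SD)².

**Latent profiles.** Each subject draws true SPI/SWI/ARB values from
truncated normals at its cell targets, and a true latency from a
moment-matched lognormal (positive and right-skewed, consistent with the
use of a non-parametric test).  The lognormal's log-scale variance is
split between subjects and within subjects (trial-to-trial) by
`within_subject_sd_frac` (default 0.5, an even split chosen in the
absence of published session-to-session variances).

**Scan synthesis.**

* Zones are i.i.d. draws from a one-preferred-zone distribution
  (preferred zone probability q, the rest uniform).  q is calibrated by
  Brent root-finding so the *expected sample* SPI — computed with a
  folded-normal approximation to the binomial zone counts, accurate to
  ~1e-3 at the scan totals used — equals the latent SPI; targets below
  the sampling-noise floor clamp to uniform use.
* Species-typical behaviours are i.i.d. draws from a power-tilted base
  repertoire (rest-dominated felid activity budget); the tilt exponent
  is solved by Brent root-finding so the distribution's entropy equals
  the latent SWI.  The family spans uniform (ln 19 ≈ 2.94 nats) down to
  near-zero entropy.
* Stereotypy bouts have geometric length with minimum = the persistence
  threshold (mean ≈ 6.9 scans at the default geometric p = 0.35), are
  placed uniformly at random without overlap (overlaps re-drawn), at a
  per-session Poisson rate calibrated so expected bout scans match the
  latent ARB fraction.  A configurable fraction of afternoon sessions
  (default 0.15) ends with a flagged pre-feeding displacement pacing
  run that a correct detector must ignore.
* Keeper ratings are a per-subject trait level (high ≈ 8 on the
  subject's own class, low ≈ 2.5 on the other, trait-level spread 0.4)
  plus independent per-rater noise (SD 0.7), rounded and clipped to
  1–9.  These defaults give inter-rater alpha ≈ 0.97 (the study reports
  > 0.8) and ≥ 95% label recovery.
* Optionally, extra subjects are appended whose repeat novel-object
  sessions straddle the 300 s cutoff, exercising the consistency screen
  (e.g. 38 generated → 35 retained).

A fixed seed yields a byte-identical CSV bundle: one generator stream is
threaded through roster, scans, ratings and trials in a fixed order.

**What the generator does *not* emulate** — and hence what passing tests
do not establish about real data: no circadian or Markovian structure in
behaviour sequences beyond bout persistence; zone choice independent of
behaviour (real pacing is spatially concentrated); no social dependence
between enclosure-mates; no observer error; no dependence of welfare on
enclosure size (real studies report a weak positive correlation of zone
bias with enclosure size).  Between-index correlations in synthetic data
arise only from the personality × origin group structure, so synthetic
correlation matrices are attenuated relative to published ones — the
published regression is therefore checked through the R² identity on the
published correlations, not through synthetic recovery.

## Problem sizes used in the test suite

The full-condition recovery check runs one study at the published design
(35 subjects × 57 one-hour sessions × 60 scans ≈ 120k scans).  The
replicate detection-rate check runs 100 studies at 12 sessions per
subject — estimation noise at 12 sessions is already an order of
magnitude below the between-subject SD for every index, so detection
rates are indistinguishable from the full design while keeping the suite
fast.  The bout-detector oracle check uses 1,000 random 200-scan
sequences with sticky behaviour transitions, recording gaps and planted
context flags.

One detection-rate assertion is expected to fail by design of the study
conditions themselves: the behaviour-diversity-by-rearing contrast has
d ≈ 1.3 at n = 16/19, i.e. ≈ 87% power at α = 0.01, so a ≥ 90% detection
bar is not attainable; the stereotypy-by-rearing contrast (d = 0.92,
published p = 0.10) is likewise only checked for being detectable above
the null rate.

## Numerical and degenerate-input choices

Calibrations use `scipy.optimize.brentq` (zone weight xtol 1e-6, entropy
tilt xtol 1e-9) with targets clamped to each family's achievable range.
SPI is undefined (raises) for zero scans; SWI for all-zero tables; alpha
for zero total variance; Cohen's d for two zero SDs; a pooled t with
zero pooled variance returns t = 0 for equal means and raises otherwise.
Report CSVs are written at 4 decimal places; all internal computation is
double precision.  The run manifest records input digests, configuration,
version and exclusions; its timestamp is the only non-deterministic
output field.
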