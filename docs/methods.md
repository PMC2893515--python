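# Methods

## The measurement model

`examsem` works in the classical test theory (CTT) frame: a candidate's
observed mark on one sitting of an examination is

    X = T + E,

where `T` is the candidate's true score (their expected mark over
hypothetical parallel sittings) and `E` is independent, zero-mean
measurement error.  Two derived quantities summarise an exam's behaviour:

* **reliability** `ρ = Var(T) / Var(X)`, estimated from item-level data by
  Cronbach's alpha, `α = k/(k−1) · (1 − Σσ_i²/σ_X²)` for `k` items with
  variances `σ_i²` and total-score variance `σ_X²`;
* **standard error of measurement** `SEM = SD·√(1 − ρ) = σ_E`, the spread
  of the marks one candidate would obtain on repeated sittings.

The package's organising claim, made assertable by simulation: the SEM is
(to good approximation) a property of the instrument alone, whereas
reliability is a joint property of the instrument and of the ability spread
of whoever happens to sit it.  Selecting candidates on a previous sitting
narrows the ability range, collapses the reliability, and leaves the SEM
unchanged.

## Two routes to the SEM

`sem_from_reliability(sd, ρ)` is the textbook formula.
`sem_first_principles(matrix)` evaluates the algebraic rearrangement

    SEM = √( (k·Σσ_i² − σ_X²) / (k − 1) ),

which never forms alpha; the two agree to 1e-10 on any matrix under one
consistent variance convention.  We use sample variances (`n − 1`)
everywhere an SD is reported, matching exam-reporting practice; alpha
itself is invariant to the convention (numerator and denominator rescale
identically), and both facts are property-tested.  The radicand is
non-negative in exact arithmetic; a floating-point-negative value is
clamped to zero and logged.

Negative alpha (possible for pathological data) is returned unchanged with
a `negative_alpha` warning in the report rather than clamped — silent
clamping would hide exactly the kind of data a reliability audit should
surface.  `sem_from_reliability` refuses reliabilities outside [0, 1]; the
first-principles route stays defined and is what `reliability_report`
records.

Item columns with zero variance (everyone right, or everyone wrong) are
legal and contribute nothing to `Σσ_i²`.  Missing cells are a declared
error, never imputed: scoring policy for absent responses belongs upstream.

## Spearman-Brown prophecy and its inversion

Lengthening a test by a factor `n` of parallel items prophesies
`r' = n·r / (1 + (n−1)·r)`.  `items_needed_for_target` inverts this for the
length factor and takes the ceiling in whole items, so the prophecy at the
returned count is ≥ the target while one item fewer falls short (the
ceiling is guarded against upward floating-point drift on exactly-attained
targets).  Worked consequence: a 260-item exam at reliability 0.83 needs
480 items to prophesy 0.9 — consistent with the "about 450" one gets by
rounding the length factor before multiplying.

## Restriction of range

For explicit selection on one variable of a bivariate-normal pair, a
correlation `r` in the full population attenuates to

    r' = r·u / √(1 − r²(1 − u²)),   u = restricted SD / unrestricted SD

(Ghiselli's classical correction).  The implementation is validated two
ways: against the printed worked value (0.9, 10, 5.85 → 0.77) and against
an explicit-truncation simulation oracle (draw bivariate-normal pairs,
select on the first variable, compare at the observed SD ratio, within
3 Monte Carlo standard errors).

`restriction_adjusted_comparison` in the tables module applies the same
formula to ask what one exam series' mean reliability would be at another
series' mean SD.  For the 2005/3-2008/3 MRCP(UK) fixtures (Part 1 alpha
0.912 at SD 10.94, taken down to Part 2's SD 6.72) the adjusted value is
0.807 — most of the Part 1 vs Part 2 reliability gap (0.912 vs 0.828) is
explained by range restriction alone.

## The Monte Carlo simulator

`SimulationConfig` defaults encode the headline study conditions: 10,000
candidates, observed mean 50 %, observed SD 10 %, reliability 0.9, pass
mark 60 %, three sittings.  The generative model is parameterised on the
*observed* moments,

    T ~ N(mean, sd·√ρ),   E_k ~ N(0, sd·√(1−ρ))  independently per sitting,

so that Var(X) = sd² and the between-sitting correlation equals ρ.  (A
model with *true* SD 10 would give observed SD 10.54 and a pass rate of
17.1 %, inconsistent with the printed observed SD ≈ 9.95 and pass rate
15.65 % that this parameterisation reproduces simultaneously; the choice is
deliberate.)  Scores are not truncated to [0, 100] — the normal model is
unbounded and truncation would bias the SDs.  A score exactly at the pass
mark passes; the boundary is measure-zero for continuous scores but must be
fixed for reproducibility.

Errors are fresh, independent draws on every sitting (nothing in the design
suggests reused error streams), and the "average restricted SD" is the
arithmetic mean of the two re-test sittings' sample SDs, not a pooled SD.

Seeding: one base seed; true scores and each administration draw from
`SeedSequence(seed, spawn_key=(stream,))` child streams, so any single
sitting is reproducible in isolation and adding sittings never perturbs
earlier ones.  Replicates derive per-replicate seeds (below 2³¹) from
`SeedSequence((base_seed, index))`.

### Analytic oracle

Every simulated statistic has a closed form used as the oracle in tests.
With standardized cut `a = (pass − mean)/sd` and hazard
`δ = φ(a)/(1 − Φ(a))`:

* pass rate `1 − Φ(a)` (0.15866 at the defaults);
* both-pass rate = the bivariate-normal orthant `P(Z₁>a, Z₂>a; ρ)`
  (0.11549), via `scipy.stats.multivariate_normal`;
* one-sided truncation shrinks the selected sitting's variance by
  `v = 1 − δ(δ − a)`; the true-score variance, regressing on it with slope
  ρ, becomes `σ_T²(1 − ρ(1 − v))`; adding fresh error variance gives the
  restricted SD (5.9268) and restricted retest correlation (0.71532);
* the SEM is exactly `σ_E = 3.1623`, untouched by selection.

The oracle was itself cross-checked once against a 12 × 10⁶-candidate
simulation during development.  Acceptance-level runs use 20 replicates at
n = 10,000 — the headline cohort size — which takes a few seconds and puts
every replicate-mean within ±3 Monte Carlo standard errors of the oracle.

## Synthetic item-level data

`item_synth` draws binary matrices from a two-parameter logistic model:
ability `θ ~ N(0, 1)` (latent units), `P(correct) =
logistic(disc_j·(θ − diff_j))`.  This is the simplest mechanism with a
monotone handle on internal consistency: discrimination 0 gives coin-flip
items and alpha ≈ 0; raising a common discrimination, or adding items,
raises alpha.  Default difficulties are `N(0, 1)`.  No guessing floor is
modelled: best-of-five guessing would add a ≈ 0.2 chance floor but none of
the downstream statistics use item-level chance levels.

`calibrate_to_alpha` bisects on a single shared discrimination in
[0, 6] until the mean alpha over a fixed block of five seeds is within
tolerance (default 0.02) of the target, raising an error carrying the best
alpha reached when the target is unattainable at the cap (e.g. alpha 0.99
on 5 items, where the Spearman-Brown bound bites).

What the generator does *not* emulate: real item banks mix
discriminations, difficulties track the candidate distribution
non-normally, abilities are not exactly Gaussian, and best-of-five items
have a guessing floor.  Passing tests therefore show the statistics are
computed correctly and behave as CTT predicts on well-specified data — not
that any real examination satisfies the model.

The committed 5 × 10 worked example is synthetic (generated once from this
model and frozen, with reference statistics computed by independent
spreadsheet-style arithmetic: alpha 0.76628, SD 2.40832, SEM 1.16428); it
is not real candidate data.

## Exam-statistics tables and the consistency audit

The bundled fixtures transcribe the published sitting-by-sitting statistics
for the MRCP(UK) Part 1 (16 diets, 2003/3-2008/3) and Part 2 (19 diets,
2002/3-2008/3) written examinations and the first eight Specialty
Certificate Examinations; their integrity is pinned by checksum in tests.
Summary rows use the **unweighted** mean and sample SD across diets —
candidate-weighting does not reproduce the published summary rows.  Blank
cells are missing, never zero, and are ignored column-wise.

The audit recomputes `sd·√(1 − alpha)` per row and flags
`|recomputed − printed| > 0.05` percentage points.  The tolerance covers
two-decimal rounding of alpha (worst-case drift ≈ `sd·0.005/(2√(1−α))`,
under 0.05 for every bundled row) while exposing larger discrepancies.
Seven Part 1 diets are flagged (2004/1, 2004/2, 2004/3, 2005/1, 2005/2,
2006/1, 2007/2; misses of 0.07-0.33 points, most plausibly SEMs computed
from unrounded alphas or directly from item data); all Part 2 and all SCE
rows reconcile within rounding.  The audit reports, it never "corrects".

## Numerical and interface conventions

* Percentages are plain numbers on the 0-100 scale everywhere.
* Display rounding is 2 dp for alpha/SEM; full precision is kept
  internally and in JSON (floats rounded to 10 dp for byte-stable output).
* CLI results go to `--out`/stdout, logs to stderr; every run writes a
  manifest (command, parameters, seed, version, timestamp) beside its
  output, and result files contain no timestamp so a fixed seed reproduces
  them byte for byte.
* Diets order lexically on (year, sitting) parsed from "YYYY/N"; SCE diets
  are bare years.

## Known limitations

* No item-response-theory estimation, no generalizability theory, no
  conditional SEM at specific score levels, and no Standard Error of
  Estimation (the regression-toward-the-mean companion statistic).
* The simulator models one pass mark and normally distributed ability
  only; standard-setting procedures are out of scope.
* The restricted-retest analytic oracle assumes selection on a single
  normal sitting; repeated or compound selection rules would need new
  truncation algebra.
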