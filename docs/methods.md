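# Methods

## The age-stage, two-sex life table

A cohort of `n01` individuals enters the table at age 0 in the first stage
(first instars less than 24 h old; the egg stage is excluded from the table
but eggs are counted as offspring — the stage order is configurable, so an
egg-start table is also expressible). Ages are whole days; the stage
recorded for a molt day is taken as authoritative, never inferred. The
final two stages are the sexed adults; sex becomes observable at a
configurable sexing stage (pupation in the default nine-stage order
L1–L6, pupa, adult female, adult male). Individuals dying before that
stage carry sex "U" and zero fecundity but contribute fully to `s_xj` and
`l_x` — the point of the two-sex method.

Definitions, with β the number of stages:

- `s_xj = n_xj / n01`; `l_x = Σ_{j=1..β} s_xj`;
- `f_xj` = eggs laid at age x by stage-j individuals ÷ `n_xj` (nonzero only
  for adult females); `m_x = Σ_j s_xj f_xj / Σ_j s_xj`, defined as 0 at
  ages with no survivors (the 0/0 case contributes nothing downstream);
- `R0 = Σ_x l_x m_x`, which conserves eggs exactly:
  `R0 = total eggs / n01`;
- Euler–Lotka: `Σ_{x≥0} e^{−r(x+1)} l_x m_x = 1`. The `x+1` exponent is
  the age-0-census / one-day-interval convention: offspring laid during
  day x enter the census at the next day boundary.
- `λ = e^r`; `T = ln(R0)/r`, returned as NaN when r = 0 (ln(R0)/r is 0/0
  there) rather than ±∞.

### Solver

`solve_r` uses bracketed bisection on the Euler–Lotka residual, which is
strictly decreasing in r: the initial bracket grows outward from [−1, 1] by
doubling until the residual changes sign, then bisection runs until the
absolute residual is ≤ 1e−12 (with a floating-point width guard). It is
deterministic and derivative-free, hence robust to spiky reproductive
schedules from small cohorts. A schedule with no reproduction (R0 = 0)
raises: r is undefined there.

### Life expectancy and reproductive value

The figures-of-merit `e_xj` and `v_xj` use the standard age-stage
recursions, evaluated empirically from the observed records:

- `e_xj` is the mean remaining days alive of the individuals observed in
  cell (x, j), **counting the current day** (an individual on its last day
  has expectancy 1; either convention is defensible, this one makes
  `e_{0,1}` equal the mean observed lifespan exactly).
- `v_xj = e^{r(x+1)} Σ_{i≥x} e^{−r(i+1)} Σ_y P(alive in (i,y) | in (x,j)) f_iy`,
  with the conditional occupation probabilities taken as the empirical
  fractions among the cell's occupants and `f_iy` the cohort fecundity
  matrix. Conditioning on a newborn recovers the Euler–Lotka sum, so
  `v_{0,1} = λ` to numerical precision — a structural identity the tests
  pin down.

Cells never occupied are NaN ("undefined"), not an error.

## Bootstrap inference

The resampling unit is the individual — a whole life history — the only
unit consistent with a life table bootstrap. Each iteration draws `n01`
individuals with replacement and recomputes r, λ, R0, T. Resamples with
R0 = 0 (no reproducing female drawn) are flagged invalid and excluded from
moments rather than mapped to r = −∞, keeping moments finite; the count of
valid draws is reported. SEs are the ddof-1 standard deviation of the valid
draws; CIs are percentile.

The paired test resamples the two cohorts independently and uses the
two-sided sign-count p-value `2·min(#{d ≤ 0}, #{d ≥ 0}) / B'`, clamped to
1, where `B'` is the number of valid differences (dividing by the full B
would bias p downward when draws are dropped). The default iteration count
is 100,000 in the CLI; the validation suite uses 500–2,000, which is ample
for the calibration and power properties it checks.

Randomness: one seed per run; per-iteration substreams are spawned
deterministically from a NumPy `SeedSequence`, so results are independent
of iteration order. For the paired test each cohort's stream is keyed by
(seed, CRC-32 fingerprint of the cohort's arrays): swapping the two cohorts
then negates every difference exactly, making the p-value exactly
swap-invariant, and comparing a cohort against an identical copy yields
d ≡ 0 and p = 1.

## The cohort simulator

The generating model is the minimal structure that produces the qualitative
shapes the analysis assumes: independent per-stage durations (fixed, or
1 + negative-binomial for overdispersed molting), daily geometric survival
per stage, sex assigned at pupation with probability `female_fraction`, and
for adult females a unimodal daily egg schedule — a discretized Gaussian
over the post-preoviposition days, normalized by largest-remainder rounding
so a fully surviving female lays `total_fecundity` eggs exactly.

Two presets bundle plausible diet phenotypes (no claim of fitting any real
data set): the corn-flour diet (larval span ≈ 20 d, pupa 10 d, daily larval
survival 0.9913 ≈ 84% to pupation, 2,658 eggs/female peaking near age 36)
and a soybean control (larval span ≈ 22 d, pupa 11 d, slightly lower
survival, 2,900 eggs/female) — chosen so the corn diet has the higher r
(faster development) while the control has the higher R0, the ordering the
economic comparison cares about.

What the simulator does **not** emulate: correlated stage durations within
an individual, mortality that varies with age inside a stage, clutch
structure or skip days in oviposition, and measurement artifacts (missed
molts, miscounted eggs). Passing tests therefore demonstrate correctness of
the estimators on data satisfying the model's assumptions, not robustness
to real-world recording noise.

For deterministic durations the expected schedules are closed-form: `l_x`
is the sex-weighted product of daily survival along the two deterministic
stage paths, and the reproductive schedule is the female path's survival
times the egg kernel; the "true" r, λ, R0, T follow. This is the oracle for
parameter recovery: on cohorts of 2,000 the estimate of r falls within 3
bootstrap SEs of the closed-form truth in ≥ 90% of replicates.

## Diet costs

Ingredient unit prices are not part of the data, so per-batch costs are
fixture values (checksummed), not recomputed from prices; arithmetic on
them is unit-agnostic (yuan per batch). Headline rounding: two decimals for
yuan, one for percent. The three design cost tiers (high/medium/low, six
formulations each) are fixed metadata.

## Trait tables

One-way ANOVA (scipy) with all-pairwise Tukey HSD comparisons in the
Tukey–Kramer form, so unequal group sizes are allowed. The compact letter
display uses insert-and-absorb; letters are assigned in descending-mean
order, a convention stated rather than universal. Degenerate input with
zero within-group variance and unequal means is flagged F = +∞ with
all-distinct letters rather than erroring. Groups need ≥ 2 observations.

## Problem sizes and tolerances

The validation suite runs at reduced scale chosen to exercise each property
with comfortable statistical slack: bootstrap B of 200–2,000 (CLI default
remains 100,000), Monte-Carlo oracles with 500–2,000 replicate cohorts,
type-I-error calibration over 200 null pairs at B = 500, and parameter
recovery over 50 replicates of n = 2,000. Floating comparisons use absolute
tolerance 1e−9 unless a tighter identity holds (Euler–Lotka residual and
conservation at 1e−12).

## Known limitations

- `e_xj`/`v_xj` are empirical-cohort estimates; no smoothing or parametric
  transition model is applied, so sparse cells at late ages are noisy.
- The paired test's sign-count p-value has the granularity 2/B; with small
  B it cannot fall below that.
- The CRC-32 cohort fingerprint used for stream keying has a 2⁻³² collision
  probability per pair; a collision would merely correlate the two sides'
  resampling.
- No population projection, timing-of-release simulation, or figure
  reproduction is included.
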