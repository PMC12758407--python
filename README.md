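# agestage

Age-stage, two-sex life table analysis for insect rearing cohorts.

## The problem

Mass rearing of beneficial or host insects (here: a noctuid moth reared on
candidate artificial diets as a host for egg-parasitoid production) is
evaluated demographically: a cohort of newly hatched larvae is followed
individually, day by day, through its larval instars, pupation and adult
life, recording stage, survival and daily egg output. The age-stage,
two-sex life table turns those records into population growth parameters
that can be compared across rearing regimes — without the female-only
survivorship bias of classical life tables, because males and individuals
dying before sex determination contribute fully to survival.

For a cohort of `n01` newborns with `n_xj` individuals alive in stage *j*
at age *x* (days):

- age-stage survival `s_xj = n_xj / n01`, age-specific survival
  `l_x = Σ_j s_xj`;
- age-stage fecundity `f_xj` (eggs per stage-*j* individual at age *x*),
  age-specific fecundity `m_x = Σ_j s_xj f_xj / Σ_j s_xj`;
- net reproductive rate `R0 = Σ_x l_x m_x`;
- intrinsic rate of increase *r*: the root of the Euler–Lotka equation
  `Σ_x e^{−r(x+1)} l_x m_x = 1` (age-0 census, one-day interval);
- finite rate `λ = e^r` and mean generation time `T = ln(R0)/r`;
- age-stage life expectancy `e_xj` and reproductive value `v_xj`
  (with `v_{0,1} = λ` as a built-in consistency check).

Standard errors come from bootstrapping whole individual life histories;
two cohorts are compared with a paired bootstrap test on the distribution of
per-iteration parameter differences. The package also ships the diet
formulation cost table used for the economic comparison, an ANOVA + Tukey
HSD compact-letter-display helper for rearing-trait tables, and a cohort
simulator with closed-form expected schedules for validation.

## Worked example

```sh
agestage simulate --seed 7 --n 100 --out diet15.csv
agestage lifetable diet15.csv --outdir lt_out
```

prints

```
r = 0.187152 per day
lambda = 1.205810 per day
R0 = 1022.7400 offspring/individual
T = 37.0301 days
```

— this simulated 100-larva cohort on the corn-flour diet preset grows by
≈ 20.6% per day (λ = 1.206) once it reaches a stable age-stage
distribution, each newborn leaves ≈ 1023 offspring on average, and a
generation takes ≈ 37 days. `lt_out/` holds the `s_xj` matrix, the
`l_x`/`m_x` schedules and the `e_xj`/`v_xj` matrices as CSV.

```sh
agestage cost CK 15
#   15 vs CK: saves 2.50 yuan (5.9% reduction)
```

i.e. the all-corn formulation 15 costs 39.82 yuan per batch against the
soybean control's 42.32 — a 5.9% saving. The same operations are available
as library calls (`simulate_cohort`, `life_table`, `bootstrap_parameters`,
`paired_bootstrap_test`, `compare_costs`, `anova_tukey`).

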