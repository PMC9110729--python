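# Methods

## The age-stage, two-sex life table

`agestage` implements the age-stage, two-sex life-table framework used in
arthropod demography to compare rearing conditions — here, prey diets for a
predatory ladybird.  A cohort of N fresh eggs is censused every 24 h until
the last individual dies; each individual's stage-transition ages, sex
(assigned at adult emergence), death age, and daily egg counts are the raw
data.  Unlike female-only age-specific life tables, the age-stage approach
keeps both sexes and all developmental stages in the bookkeeping, so
variable development rates and pre-adult mortality propagate correctly into
the population parameters.

Ages are integer days with age 0 the day of oviposition; an individual with
death age d is observed alive on days 0..d−1.  The egg stage is part of the
cohort, so "immature duration" runs from oviposition to adult emergence.

### Schedules

For stage j and age x (the adult stage split by sex):

- `s_xj` — probability that a fresh egg is alive and in stage j at age x,
  estimated as the occupancy count divided by N.  Every entry is a multiple
  of 1/N.
- `l_x = Σ_j s_xj` — age-specific survival; `l_0 = 1`, non-increasing.
- `f_xj` — eggs laid at age x per adult female alive at age x (zero for all
  other stages).
- `m_x = Σ_j s_xj f_xj / Σ_j s_xj` — population mean daily egg output among
  survivors, defined as 0 where no one is alive.

### Scalar parameters

- Net reproductive rate `R0 = Σ_x l_x m_x`.  Algebraically this equals
  F · N_f / N, mean eggs per female times the female fraction of the cohort;
  the two computations are kept as an internal cross-check.
- Intrinsic rate of increase `r` solves the Euler–Lotka equation with age
  indexed from 0:

      Σ_x exp(−r (x+1)) l_x m_x = 1

  The (x+1) exponent is deliberate and documented because an off-by-one in
  the discount age shifts r in the third decimal at these time scales.
- Finite rate `λ = e^r`; mean generation time `T = ln(R0)/r`.
- Age-stage life expectancy `e_xj`: expected remaining days of life of an
  individual alive in stage j at age x, computed from the empirical
  trajectories as the mean of (death age − x) over the individuals observed
  in (x, j).  `e` at age 0 in the first stage equals the cohort mean
  lifespan, deaths included.
- Age-stage reproductive value `v_xj`: the present value, under exponential
  growth at rate r, of the expected future egg stream of an individual in
  (x, j):

      v_xj = e^{r(x+1)} · mean_{i in (x,j)} Σ_{a ≥ x} e^{−r(a+1)} eggs_i(a)

  The Euler–Lotka identity makes `v` at age 0 in the first stage exactly λ;
  the test suite asserts this on every cohort with R0 > 0.

On a cohort with no reproduction (the *T. evansi* diet kills every larva in
the fourth instar) R0 = 0 and r, λ, T and v are reported as undefined — NaN
in the API, the string `undefined` in CLI tables — while s_xj, l_x and e_xj
are still computed.

### Numerical choices

- The Euler–Lotka root is found by log-space bisection on r ∈ [−5, 5]
  (monotone, overflow-safe via log-sum-exp) followed by Newton polishing
  with the analytic derivative; converged residual < 1e−12, typically
  ~1e−16.  Tests cross-check against an independent bracketed root-finder.
- `m_x` at ages where `l_x = 0` is defined as 0 so it never contributes.
- Unoccupied (x, j) cells of `e_xj`/`v_xj` are NaN, not 0.
- Stage-duration means use completers only (individuals that entered the
  next stage); the truncated occupancy of the death stage still counts in
  the survival schedules.  This matches how survivor counts are reported in
  cohort tables.
- Female/male longevity is reported under both conventions — adult lifespan
  (emergence→death) and total lifespan (egg→death) — because published
  tables are ambiguous about which is meant.

## Bootstrap inference

The resampling unit is the individual: each replicate draws N individuals
with replacement and recomputes the statistic, re-solving Euler–Lotka for
r-type statistics.  Standard errors are replicate SDs; intervals are
percentile 95% CIs (no bias correction).  Two treatments differ when the
95% percentile interval of the replicate differences (arms resampled
independently, with independent seed substreams) excludes zero; with ≥3
treatments a compact letter display is derived from the maximal cliques of
the not-significantly-different graph.

Replicates on which a statistic is undefined — an all-male resample has no
fecundity, APOP, or r — are skipped and counted in `degenerate_count`, with
a warning when they exceed 1% of B.  Skipping is the least biased default
and the count keeps it auditable.  The study-scale default is B = 100,000;
tests and examples run at B ≤ 5,000, which changes SEs by well under the
Monte-Carlo noise of interest.

Whether paired resamples should be coupled across treatments by index is
not determinable from the published description; arms are resampled
independently here.

## Synthetic cohorts

The generator emulates the four prey-diet assays (cohorts of 50 eggs,
daily census, stage sequence egg→L1→L2→L3→L4→prepupa→pupa→adult) so the
whole pipeline is testable without the unpublished raw data.  Presets
encode the reported treatment means: per-stage duration means and SEs
(SD recovered as SE·√n), per-stage completion probabilities from the
survivor counts, sex ratio, APOP, oviposition days, per-female fecundity,
and adult longevity.  The *T. evansi* preset sets the fourth-instar
completion probability to 0, so no individual ever pupates; its unreported
egg and L4 duration means borrow the neighbouring diets' values (3.0 and
4.3 d), which only affect death timing.

Distributional choices, and what they do not emulate:

- **Durations** are 1 + a gamma draw with the target mean and SD,
  stochastically rounded (floor + Bernoulli on the fractional part) to
  whole days.  Stochastic rounding keeps configured means exact — the
  parameter-recovery suite checks grand means over 300 cohorts within 2
  Monte-Carlo SEs — at the price of slightly inflated dispersion.
  A printed SE of 0.0 yields a constant duration.
- **Within-stage deaths** occur on a uniformly drawn day inside the stage;
  the daily census gives no information about actual death timing.
- **Sex** is Bernoulli with the observed female fraction among adults;
  immature deaths stay unsexed, as in the assays.
- **Adult longevity** uses the adult-only reading of the reported
  female/male longevities.  That reading reproduces the reported cohort
  mean total lifespans (e.g. ≈38.7 d on the poor diet, ≈107 d on the good
  diets) when combined with the immature durations, while the egg-to-death
  reading does not.  Every emerged female is conditioned to outlive her
  pre-oviposition period, since all observed females oviposited; this
  raises the realized female longevity slightly above the configured mean
  on the short-lived diet.
- **Fecundity** uses a two-piece "plateau + decay" daily-egg curve:
  uniform from the mean total pre-oviposition age to the reported peak
  age, then linear decay to the end of the laying window (mean emergence +
  mean female adult longevity).  A single shape parameter — the fraction
  of egg mass in the plateau — is calibrated in closed form so the
  idealized schedule solves the Euler–Lotka equation exactly at the
  reported r given the reported R0.  A triangular rise to the peak age was
  considered and rejected: the reported {TPOP, peak age, R0, r} jointly
  require heavy egg deposition immediately after first oviposition, and no
  curve rising linearly to a peak 30+ days later can reach the reported r
  (it undershoots by ~20%).  The calibrated plateau family reproduces the
  reported daily-egg peak heights to within ~5% as an emergent property.
  Each female's lifetime total is drawn around the fecundity target and
  allocated multinomially over her realized laying days (Bernoulli-thinned
  to hit the mean oviposition-day count), so per-female totals average the
  target exactly; females dying early compress their schedule rather than
  truncate it.
- **Not emulated**: between-individual correlation of development speed
  and fecundity, day-to-day autocorrelation of egg laying, the empirical
  (non-parametric) shape of the real fecundity curves, and any diet-switch
  dynamics.  Passing recovery tests therefore demonstrates that the
  pipeline is unbiased for cohorts of this structure, not that the
  generator reproduces every feature of the real assays.

## Validation scale

The recovery suite simulates 300 cohorts of n = 50 per preset (~10 s); the
bootstrap behaviour suite uses B = 50,000 for the closed-form SE check, 500
null repetitions at B = 1,000 for the type-I error rate, and 300
repetitions at B = 600 for CI coverage.  `scripts/acceptance.py` re-runs
the 300-cohort aphid-diet recovery and a deterministic count fixture; both
finish in well under a minute.

## Known limitations

- Bootstrap SEs of the published tables cannot be reproduced exactly: the
  underlying individual records were never deposited, so all quantitative
  validation runs against calibrated synthetic cohorts or printed-value
  identities.
- The e_xj/v_xj recursions condition on empirical per-individual
  trajectories; they are undefined (NaN) at never-occupied (x, j) cells
  rather than smoothed.
- The letter display is exact for the handfuls of treatments this design
  uses; its brute-force clique search is exponential in the number of
  treatments and not meant for dozens of groups.
- No multiple-testing correction beyond the letter display is applied,
  matching the published analysis.
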