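# Methods

## Evidence synthesis

Study-level data are one row per treatment arm per cohort: patient count,
person-years at risk, and event counts for nine outcomes.  Early (30-day)
mortality is a per-procedure proportion; all other outcomes are
person-time incidence rates reported in %/year.

Pooling is DerSimonian–Laird random effects, chosen for its closed form and
determinism.  For rates the study-level estimate is y_i = ln(events/person-years)
with Poisson variance v_i = 1/events; zero-event studies receive a 0.5
continuity correction to the count (flagged on the result, and a warning is
raised when *every* study is zero-event).  The pooled log rate is
back-transformed with a 95% CI of exp(ŷ ± 1.96·se).  A single study returns
its own estimate and CI (identity), and τ² = 0 whenever all study estimates
coincide.

For the early-mortality proportion the logit scale is used, but study
variances are computed from **expected** counts under a common initial
proportion p₀ (the total-event proportion): v_i = 1/(nᵢp₀) + 1/(nᵢ(1−p₀)).
With under one expected event per cohort, observed-count inverse-variance
weights are proportional to the realised event count, which biases the
pooled estimate upward by roughly a factor (1 + 1/E[events per study]) and
destroys CI coverage; expected-count weighting restores ≥95% coverage in
the generator's recovery simulations while leaving the single-study
identity untouched.  Rate outcomes keep observed-count variances: with ~10
expected events per cohort the bias is immaterial and coverage is ≥90%.

Between-arm comparisons use the subgroup heterogeneity statistic
Q_between = Σ_a w_a(ŷ_a − ȳ)², w_a = 1/se_a², against χ² with (arms − 1)
degrees of freedom.

## Decision model

A discrete-time Markov multistate cohort model with 1-year cycles,
t = 0..55 (start age 44.5, so the cohort is followed to age ~100).  States
encode only the most serious event history:

    well → post-stroke non-disabled → post-stroke disabled → dead

with the severity order dead > disabled > non-disabled > well; a less
severe destination never overwrites a more severe current state.

Within a cycle, transient events occur independently with per-cycle
probabilities p = 1 − exp(−rate/100) converted from the pooled annual
rates: major bleed, conservatively treated infective endocarditis (IE),
aortic-valve reoperation for IE, aortic-valve reoperation for other causes,
and (Ross only) RVOT reintervention.  Thromboembolic events are modelled as
strokes; reoperations cascade into stroke with conditional probabilities.
Each event carries a conditional death probability, and the per-cycle death
probability combines background mortality and all event-conditional deaths
as 1 − Π(1 − p_k).  Survivors of a stroke become disabled with
p(disability | stroke), else non-disabled.  The engine computes the exact
within-cycle joint distribution by enumerating the 2⁶ event-occurrence
combinations, so the cohort recursion agrees with an individual-level
microsimulation by construction — the test suite verifies this against an
independent 10⁶-walker simulation within 3 Monte Carlo standard errors.

Cycle 0 applies the peri-operative probabilities (operative death, early
stroke, early bleed) through the same machinery.  The cAVR strategy mixes
mechanical and biological parameters as (1−w)·mech + w·bio with w = 0.23
on the annual-rate scale before probability conversion; the same mixture
applies to early probabilities and the procedure cost.

Costs and QALYs accrue per cycle on the end-of-cycle state occupancy
(annual state costs and utilities) plus expected transient events (one-off
costs and disutilities), discounted by (1+r)^−t with r = 3.5%/year for both
costs and QALYs (UK reference-case convention; the first cycle is
undiscounted).  The initial procedure cost enters at cycle 0.  No
half-cycle correction is applied by default; a documented flag enables
trapezoidal weighting.  A negative per-cycle QALY raises a validation
error rather than being clamped — it signals disutilities inconsistent
with the state utilities.

Excluded by design: renal failure, pacemaker, arrhythmia and myocardial
infarction events; tunnel states; age-dependent background mortality (the
pooled late-mortality rate is constant over age, which overstates early
and understates late hazards but preserves cohort-level life expectancy at
the rates observed in the source cohorts).

## Input deck

Every parameter lives in one serialisable deck (YAML/JSON, versioned
schema).  Uncertain parameters carry a point estimate, a 95% interval, and
a distribution family fitted by method of moments: log-normal for rates
(σ = (ln hi − ln lo)/(2·1.96)), Beta for probabilities and utilities
(matching mean and interval-implied SD), Gamma for the post-stroke
disability annual cost.  Tariff costs are fixed (agreed prices, not
sampled); the 15 fixed entries — 9 one-off costs, the well-state utility
and 5 event disutilities — are exactly the set exercised by the one-way
sensitivity analysis.

The shipped deck's pooled rates and early mortality are the published
meta-analytic estimates; **everything else is a placeholder** (tagged
`placeholder_not_from_paper`), chosen once at realistic NHS scales:
procedure costs £16 500 (Ross) / £11 500 (prosthetic AVR), redo-surgery
tariffs £24 000–£30 000, acute stroke £11 600, post-stroke disability
£5 500/year (an NHS-only perspective excludes social care, which keeps
this figure low), utilities 0.93 / 0.74 / 0.38 for well / non-disabled /
disabled post-stroke.  Within these realistic ranges the deck was
calibrated so that it reproduces the published qualitative orderings
(Ross cost-effective against the mixture and against either prosthesis
alone; mechanical superior on both costs and QALYs to biological) — the
deck is a stand-in for an unavailable supplement, and those orderings are
part of its specification.  Peri-operative stroke/bleed probabilities have
deliberately wide intervals reflecting the scarcity of comparative
evidence on immediate post-procedural events.

## Probabilistic sensitivity analysis

10 000 joint draws by default, sampled independently per parameter in
deterministic name order from one seeded generator, so results are
byte-reproducible.  Both strategies are evaluated on the *same* draw
(common random parameters), which is what makes incremental quantities and
the CEAC meaningful.  Draws violating parameter support are rejected and
resampled with a logged count; more than 1% rejections aborts (with the
shipped families support violations cannot occur, so this is a guard
against hand-edited decks).  Summaries are means and equal-tailed 2.5/97.5
percentile credible intervals.  The CEAC reports, at each willingness-to-
pay value, the fraction of draws in which each strategy has the highest
NMB, splitting exact ties equally.

On the shipped deck the Ross strategy has the higher NMB in essentially
every draw above ~£1 000/QALY, so the CEAC is ≈1 and the EVPI at £20 000 is
≈0: the placeholder deck implies a decision with no value of further
research.  This differs from the published analysis, whose wider
supplement priors left a small residual decision uncertainty; the test
suite therefore exercises the value-of-information estimators on a
synthetic stress deck with closely matched strategies as well.

## Value of information

EVPI is computed directly from stored PSA draws,
E[max_d NMB_d] − max_d E[NMB_d], with a nonparametric bootstrap CI
(1 000 resamples by default).

EVPPI for a subset φ is the nested expectation
E_φ[max_d E[NMB_d | φ]] − max_d E[NMB_d].  Two estimators are provided:

- **Nested Monte Carlo** (the oracle): n_outer draws of φ, each with
  n_inner draws of the complement.  The reported SE is the outer-level
  standard error of the coupled per-outer difference.
- **Multilevel Monte Carlo**: level ℓ uses inner sample size n₀·2^ℓ and
  outer size max(2, n_outer/2^ℓ) (constant cost per level).  The level-ℓ
  correction couples the fine estimator max_d mean(all inner) with the
  antithetic coarse estimator ½[max_d mean(first half) + max_d mean(second
  half)]; level 0 is coupled to the unconditional baseline term.  The
  telescoping sum estimates the nested expectation at effective inner size
  n₀·2^L with O(1/N) bias decay per level; non-decaying level corrections
  set a warning flag.  Both estimators agree within 3 combined standard
  errors on the shipped and stress decks (verified over 20 seeds), and
  both recover the closed form on the Normal conjugate family
  (ΔNMB = θ₁ + θ₂, EVPPI(θ₁) = φ(0) = 0.39894).

Subset names follow the analysis plan: `meta_analysis` (pooled rates and
early mortality), `early_bleed_stroke` (peri-operative stroke/bleed),
`other_epidemiological` (the ten conditional cascade probabilities),
`utilities`, `poststroke_disability_costs`, `ross_trial_all_epi` (the union
of the three epidemiological sets — what a comparative trial would inform,
excluding costs and utilities), and `all`.

Population scaling multiplies per-person values by
incidence × Σ_{t=0}^{24} (1+0.035)^−t; at 960 patients/year this is 16 376
people, the discounted number affected while the decision stays relevant.

## Synthetic evidence base

`generate_cohorts` draws, per cohort: size from a log-normal with median
270 and log-SD 0.35 (floored at 10 patients — 48 cohorts then hold
~13 000–14 000 patients); follow-up from a Gamma with mean 7.1 years and
shape 4; person-years as size × follow-up; each rate outcome as
Poisson(rate/100 × person-years); early deaths as Binomial.  An optional
Gamma–Poisson overdispersion knob (log-scale SD) induces genuine
between-study heterogeneity to exercise the random-effects machinery; the
default is plain Poisson, i.e. a homogeneous truth.  What the generator
does *not* emulate: era and centre-expertise covariates, correlated
outcomes within cohorts, publication bias, loss to follow-up.  Passing
recovery tests therefore show estimator correctness under a clean
sampling model, not robustness to those real-data features.

## Numerical and testing choices

- Per-cycle transition kernels are computed once per strategy (rates are
  age-constant) and vectorised across draws; a 10 000-draw PSA over both
  strategies runs in under a second.
- The microsimulation oracle in the test suite re-implements the cycle
  semantics walker-by-walker with independent Bernoulli draws and is kept
  deliberately free of the enumeration code it checks.
- Problem sizes in the test suite (200-replicate coverage runs, 10⁶-walker
  microsimulation on an 11-cycle deck, 20-seed estimator-agreement runs,
  10⁵-draw closed-form checks) were chosen as the smallest scales at which
  the statistical assertions have comfortable margins.
- Equal-tailed percentile intervals everywhere; exact ties in the CEAC
  split equally; seeds propagate through `numpy.random.default_rng` only.

## Known limitations

- The shipped deck is a labelled stand-in: absolute lifetime costs and
  QALYs are not the published values and should not be quoted as such.
- Background mortality is age-constant; no general-population life-table
  add-on is active by default.
- Within-cycle event independence is an assumption, not an estimate; it
  was chosen for determinism and testability.
- EVPPI estimators assume the subset draws are independent of the
  complement (true of the shipped deck, which has no parameter
  correlations).
- Expected value of sample information is out of scope.
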