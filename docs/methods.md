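# Methods

## The decision problem

An envenomed snakebite patient in one of 16 West African countries either
has access to an effective antivenom or does not. The model is a
single-episode decision tree evaluated per country from a public-payer
perspective: no time steps, no Markov states, one treatment decision with
chance nodes for snake type, early adverse reaction (EAR), death, and
amputation. Outputs are expected cost and expected health loss per patient
in each arm; the headline statistics are the incremental cost-effectiveness
ratios (ICERs) — incremental cost per death averted and per
disability-adjusted life year (DALY) averted — classified against a
willingness-to-pay threshold of one times the country's GDP per capita
(strictly below the threshold counts as cost-effective).

## Tree structure and conventions

A bite is caused by a carpet viper (*Echis* spp.) with probability `p_cv`.
In the treated arm the 20-minute whole blood clotting test triages the
patient: coagulopathy (carpet viper) leads to monospecific antivenom with
EAR risk `p_ear_mono`; otherwise a polyspecific antivenom is given with EAR
risk `p_ear_poly`. Antivenom multiplies the untreated case fatality of the
patient's branch by `(1 − effectiveness)`. The untreated arm has no triage,
no EAR, and (base case) no cost.

Conventions that the source material leaves open, fixed here and isolated
in the code:

* **EAR-death compounding.** An EAR carries its own 1% mortality. We
  compound it independently with the residual envenoming mortality: a
  treated patient on a branch with post-antivenom mortality `p` and EAR
  risk `e` dies with probability `e·(m + (1−m)·p) + (1−e)·p`, `m` the EAR
  mortality. The convention lives entirely in
  `tree.branch_death_probability` and can be swapped. The alternative —
  counting no EAR deaths — reproduces some published country results
  slightly better and others (the two countries using high-EAR EchiTab
  products) clearly worse.
* **Costs.** Every treated patient incurs the antivenom, the ten clotting
  tests, supportive care, feeding/transport, and refrigeration/transport
  items (USD 237.375 in total); EAR management (USD 1.875) is weighted by
  the branch-mixture EAR probability. Patients who die of an EAR incur the
  full bundle (treatment was given). Costs are never discounted: the
  episode lasts days.
* **Amputation.** Survivors of either arm lose a limb with probability 3%;
  antivenom has no effect on amputation in the base case. Because
  treatment creates survivors, the treated arm has *more* expected
  amputations — the incremental amputation term is negative and is carried
  through the DALY arithmetic rather than clamped.

## DALY arithmetic

Health outcomes are discounted at an annual rate r = 3% with the discrete
end-of-year annuity A(L, r) = Σ_{t=1..L} (1+r)^(−t) = (1 − (1+r)^(−L))/r,
where L is the integer remaining life expectancy at the mean age of bite
(25–29 years; L ranges from 37 to 45 years across the countries). A death
costs A(L, r) years of life lost (22.17–24.52 discounted years across the
table); a lifelong amputation costs 0.102 · A(L, r) (2.26–2.50 years). The
discrete annuity — not continuous e^(−rt) discounting — is used because it
reproduces those reference constants exactly. No age-weighting is applied,
and the disability runs for the full remaining life expectancy. EAR deaths
receive the same YLL as envenoming deaths (same cohort, same L). The
annuity is computed via `expm1`/`log1p`, so it is stable down to r → 0 and
equals L in that limit.

## Inputs

The 16-country table ships with the package
(`snakebite_cea/data/countries.csv`): snake-mix proportion, untreated case
fatality by snake type, antivenom effectiveness by branch, EAR risks, GDP
per capita, and remaining life expectancy. Points worth flagging:

* Liberia and Sierra Leone carry `p_cv = 0.01` in the base case; their
  reported 0% is analysed as the separate snake-mix scenario.
* Five countries (Cameroon, Chad, Ghana, Côte d'Ivoire, Gambia) have no
  reported untreated non-carpet-viper mortality; the packaged table uses
  5%, the value that makes the per-country results internally consistent
  with the published grid (independently confirmed by three countries with
  identical life expectancy and effectiveness printing identical snake-mix
  scenario ICERs).
* Benin, Guinea-Conakry and Guinea-Bissau use the elapid-specific
  effectiveness estimate 43.6% on the non-carpet-viper branch; all other
  countries reuse their carpet-viper effectiveness there (dropping that
  assumption is the `ncv_eff_zero` scenario).
* Countries without a product-specific EAR estimate use the 4.3% median;
  Nigeria and Burkina Faso assign EchiTab-G's 19% to the monospecific
  branch and EchiTab-Plus's 26% to the polyspecific branch.

Costs are stored to the cent as reported, with no currency-year adjustment.

## Scenarios and one-way sensitivity

Scenarios are declarative override bundles applied to immutable input
copies: antivenom price at $125 or $306, snake-mix proportion 0, nil
non-carpet-viper effectiveness, a $65.63 comparator-arm care cost,
adrenaline premedication (both EAR risks × 0.6), and substitution of
amputation by venom-ophthalmia blindness (0.01%, weight 0.552) or PTSD
(20%, weight 0.105). Absolute overrides are idempotent and compose across
disjoint fields.

The tornado varies one input at a time. Default ranges: the cross-country
envelopes of the reported base-case values for the probability inputs
(e.g. snake mix 1–85%, carpet-viper mortality 8.1–15.83%, EAR risks
3.3–19% / 3.3–26%); $125–$306 for the antivenom price (the two published
price scenarios); ±20% for the other cost items; 0–2% for EAR mortality
and 1–6% for amputation risk (plausible spans — none are reported). ICERs
are monotone in the directions one expects: decreasing in effectiveness,
increasing in every treated-arm cost. EAR-related inputs are negligible
drivers (<5% of the top driver's spread) in 14 of 16 countries; in Liberia
and Sierra Leone, where 99% of envenoming is non-carpet-viper, sweeping
the polyspecific EAR risk to 26% moves enough EAR deaths to reach ~7% of
the top spread. That structural exception is asserted as such in the test
suite.

## Probabilistic sensitivity analysis

Sixteen inputs are drawn jointly and independently per iteration (the seven
country probabilities, EAR mortality, amputation risk, the amputation
disability weight, and six cost items; the comparator cost is never
varied). Only distribution *families* are reported for these inputs, so the
parameterisation is the package's, recorded on every spec object:

* A probability with a reported envelope and an interior base value gets a
  Beta with mean fixed at the base value and concentration fitted
  numerically so its 2.5/97.5% quantiles approach the envelope
  (`quantile_fit`). An asymmetric interval around a fixed mean can only be
  matched approximately; the fit is accepted up to 0.05 absolute quantile
  error, else the modified-PERT construction on (low, base, high) is used
  (`pert`).
* A base value sitting *on* an envelope bound (e.g. Liberia's 1% snake
  mix) gets a moment-matched Beta centred at the base with a 25%
  coefficient of variation rather than a distribution shifted into the
  envelope's interior: the envelopes are spans of base-case values across
  countries, not per-country sampling intervals, and the published
  per-country PSA intervals are only reproducible with distributions
  centred at each country's own value.
* Effectiveness uses the country's reported confidence bounds where
  available (e.g. Nigeria 87–95%), else the cross-country envelope; a
  switch exposes the all-envelope alternative.
* Unranged probabilities (EAR mortality 1%, amputation 3%, weight 0.102)
  get moment-matched Betas at 25% CV. Costs get Normal(mean, 0.20·mean)
  truncated at zero — the dispersion is a package default, flagged in
  logged output.

Each iteration evaluates the same closed-form tree, vectorised across
draws. Draws violating invariants are resampled (capped); iterations where
the treatment averts no DALYs are dominated and carry an infinite ICER,
which counts against cost-effectiveness and sits at the top of the
percentile ordering. One seeded generator drives a run, sampling in a fixed
field order, so results are reproducible and independent of evaluation
order. The acceptability curve reuses one shared draw set across the whole
willingness-to-pay grid and is therefore non-decreasing by construction.

At 10,000 iterations the per-country probability of cost-effectiveness at
1× GDP ranges from ~92% (Liberia) to 100%, and every deterministic
base-case ICER lies inside its 95% PSA interval. The published
probabilities (97.3–100%) imply narrower input dispersions than our
defaults; with only families reported, we kept the documented defaults
rather than tuning dispersion to match.

## Microsimulation oracle and synthetic parameters

`oracle.simulate_cohort` pushes individual patients through the identical
branch structure with one uniform draw per chance node and returns
empirical means with standard errors; `oracle.oracle_icer` forms ICERs
from two cohorts, by default with common random numbers across arms
(variance reduction), and reports delta-method standard errors. At two
million patients per arm, analytic and simulated arm outcomes and ICERs
agree within three standard errors for all 16 countries and for 20 random
synthetic parameter sets drawn uniformly within the cross-country
envelopes (`generate_country_params`, always valid by construction).

The synthetic generator emulates the *parameter* universe of this analysis
— its study data are parameter tables, not patient records — so passing
property tests demonstrate the pipeline's correctness and stability across
the plausible input space, not the epidemiological accuracy of any
particular synthetic country.

## Problem sizes and determinism

The deterministic 16-country grid with all scenario columns evaluates in
well under a second. PSA uses 10,000 iterations per country (seconds for
all 16); the oracle checks use 2×10⁶ patients per arm (~1 s per country).
All stochastic entry points take explicit integer seeds; identical
configuration yields byte-identical outputs.

## Known limitations

* The EAR-death compounding convention is one of several algebraically
  reasonable readings; reproduction residuals against the published grid
  (≤1.9%, most ≤0.5%) partly reflect that choice.
* PSA dispersions for costs and unranged probabilities are package
  defaults; reported probability-of-cost-effectiveness values depend on
  them and are reproduced as bounds, not point values.
* The model has no severity stratification, no venom-dose effect, no
  multi-dose logic beyond the price scenario, and treats the meta-analytic
  effectiveness as exchangeable across countries without their own data.
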