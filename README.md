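# vaxavert

How many infections or deaths did a vaccination program avert among the
people it vaccinated? When rollout happens over time, surveillance studies
usually answer with a *hazard-difference* calculation: each week, multiply
the number of vaccinated survivors by the difference between unvaccinated
and vaccinated hazards, then sum. `vaxavert` implements the causal estimand
that calculation is aiming at, an estimator that actually hits it, and the
machinery to measure how far the hazard-difference shortcut misses.

It is written for epidemiologists and biostatisticians working on
vaccine-impact estimation: the library exposes the estimand/estimator
algebra on exact rational arithmetic for trial-scale data, a stratified
SIRD simulator for population-scale bias studies, an exact
finite-population enumeration oracle, and a small CLI.

## The quantities

With `N` individuals randomized at baseline to vaccination times
`x ∈ {0, …, q+1}` (`q+1` = never vaccinated) under proportions `ρ`, and
`Ȳ_l(x)` the group-average cumulative incidence of arm `x` before interval
`l`, the **direct impact** of the rollout versus no vaccination is

    δ^D = N · Σ_{x=0}^{q} ρ_x · [ Ȳ_{q+1}(q+1) − Ȳ_{q+1}(x) ]

— outcomes averted among the vaccinated by their own vaccination, holding
the rest of the program fixed. Its plug-in with arm-level sample
incidences is exactly unbiased in a one-stage randomized trial, even under
interference. The hazard-difference estimator

    δ̂^D* = Σ_k N̂_k^v · ( ĥ_{k+1}^u − ĥ_{k+1}^v )

is biased whenever the vaccine works: susceptibles deplete faster among
the unvaccinated, so the late unvaccinated hazards describe a group whose
survival no longer matches the vaccinated survivors they are multiplied
with. The package also provides an aggregated-data estimator that repairs
this weighting (unbiased in expectation with the same data requirement),
the avertible-outcome analogues for the never-vaccinated, and the overall
impact against a no-vaccination counterfactual run, which the direct impact
bounds from below when the indirect effect is non-negative.

## Worked example

Six participants, one third each assigned to vaccination at day 0, day 60,
or never; arm cumulative incidences at the end of follow-up are 0, 1/2
and 1:

```python
>>> import vaxavert as vx
>>> records, strategy, n = vx.figure1_fixture()
>>> arm = vx.arm_incidence_from_records(records, strategy)
>>> vx.unbiased_estimator(arm)
Fraction(3, 1)
>>> table = vx.status_table_from_records(records, strategy)
>>> vx.hazard_difference_estimator(table)
Fraction(4, 1)
```

The unbiased estimator reports **3** directly averted outcomes
(`6·[⅓·(1−0) + ⅓·(1−½)]`). The hazard-difference estimator reports **4**
from the very same six people (`2·(½−0) + 3·(1−0)`): it weights the
interval-1 unvaccinated hazard (1, one event in one survivor) by the three
vaccinated survivors, ignoring that the unvaccinated arm has been depleted
faster. The same numbers are available from the shell:

```sh
$ vaxavert fixture --name figure1 --out figure1.csv
$ vaxavert estimate --table figure1.csv --estimator unbiased
3
$ vaxavert estimate --table figure1.csv --estimator hazard-diff
4
```

At population scale, a scenario run compares the estimand with the
hazard-difference expectation under a two-time rollout (20 % at day 0,
30 % at day 60, R0 ≈ 3.57, one million people):

```sh
$ vaxavert simulate --scenario 1
scenario 1 infection: estimand=140489 hd_expectation=149063
scenario 1 death: estimand=1404.88 hd_expectation=1405.15
```

With 90 % efficacy against infection the hazard-difference method
overstates averted infections by ~6 % here, while averted deaths are
essentially unbiased at a 1 % infection-fatality rate.
`vaxavert bias-table --scenarios 1-9 --out bias.csv` writes the full grid;
`vaxavert.beta_sweep` and `vaxavert.pathogen_preset` cover the sensitivity
analyses. See `docs/methods.md` for the model, its assumptions, and the
regimes where the bias mechanism saturates.

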