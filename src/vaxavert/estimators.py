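"""Sample-data estimators for directly averted (and avertible) outcomes.

Four estimators are provided for the direct-impact estimand of
:mod:`vaxavert.estimands`:

* :func:`unbiased_estimator` — the plug-in of the estimand formula using
  arm-resolved sample cumulative incidences; exactly unbiased under a
  one-stage randomized trial with a mixed assignment strategy.
* :func:`hazard_difference_estimator` — the estimator used by many
  empirical rollout-impact studies: per interval, (vaccinated survivors)
  times (not-yet-vaccinated hazard minus vaccinated hazard), summed over
  intervals.  Biased whenever vaccination has a non-null effect, because
  susceptibles are depleted faster in the unvaccinated group and the
  unvaccinated hazard therefore applies to a population with different
  survival.
* :func:`alt_unbiased_estimator` — an estimator with the same
  status-aggregated data requirement as the hazard-difference estimator,
  obtained by reweighting its late not-yet-vaccinated hazard terms by
  unvaccinated (rather than vaccinated) survivors.  Its expectation over
  the randomization distribution equals the estimand.
* :func:`avertible_hd_estimator` — the hazard-difference analogue for
  outcomes avertible among the unvaccinated (weights are unvaccinated
  survivors).

:func:`hd_expectation` evaluates the closed-form large-sample expectation of
the hazard-difference estimator on population-truth incidences, which is how
its bias is quantified against the estimand.

All functions preserve exact :class:`fractions.Fraction` arithmetic when the
inputs are exact (counts, rational proportions) and fall back to floats for
simulation-scale inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from . import estimands
from .trial_data import (
    ArmIncidence,
    IndividualRecord,
    Number,
    StatusTable,
    Strategy,
    arm_incidence_from_records,
    exact_div,
    status_table_from_records,
)

__all__ = [
    "HazardComponents",
    "unbiased_estimator",
    "hazard_components",
    "hazard_difference_estimator",
    "alt_unbiased_estimator",
    "avertible_hd_estimator",
    "hd_expectation",
    "hd_bias",
    "unbiased_from_records",
    "hd_from_records",
    "alt_unbiased_from_records",
    "avertible_hd_from_records",
]


@dataclass(frozen=True)
class HazardComponents:
    """Per-interval ingredients of the hazard-type estimators.

    Index ``k`` runs over intervals ``0..q``.  ``n_vax[k]`` / ``n_unvax[k]``
    are survivors at the beginning of interval ``k`` among vaccinated /
    not-yet-vaccinated individuals; ``h_vax[k]`` / ``h_unvax[k]`` are the
    corresponding hazards during interval ``k`` (the paper-style hazard "one
    interval ahead of the survivors").
    """

    n_vax: tuple
    n_unvax: tuple
    h_vax: tuple
    h_unvax: tuple

    def __post_init__(self):
        lengths = {len(self.n_vax), len(self.n_unvax), len(self.h_vax), len(self.h_unvax)}
        if len(lengths) != 1:
            raise ValueError("component sequences must share one length")
        for h in list(self.h_vax) + list(self.h_unvax):
            if h < 0 or h > 1:
                raise ValueError(f"hazard {h!r} outside [0, 1]")

    @property
    def n_intervals(self) -> int:
        return len(self.n_vax)


def _hazard(events: Number, at_risk: Number, what: str) -> Number:
    """events / at_risk, with the 0/0 convention -> 0 (warned)."""
    if at_risk == 0:
        if events == 0:
            warnings.warn(
                f"empty risk set for {what}; defining hazard 0/0 := 0",
                RuntimeWarning,
                stacklevel=3,
            )
            return 0
        raise ZeroDivisionError(
            f"{what}: {events!r} events in an empty risk set"
        )
    return exact_div(events, at_risk)


def hazard_components(table: StatusTable) -> HazardComponents:
    """Survivor counts and interval hazards from a status-aggregated table."""
    n_vax, n_unvax, h_vax, h_unvax = [], [], [], []
    for row in table.rows:
        n_vax.append(row.vax_at_risk)
        n_unvax.append(row.unvax_at_risk)
        h_vax.append(_hazard(row.vax_events, row.vax_at_risk,
                             f"vaccinated group, interval {row.interval}"))
        h_unvax.append(_hazard(row.unvax_events, row.unvax_at_risk,
                               f"not-yet-vaccinated group, interval {row.interval}"))
    return HazardComponents(tuple(n_vax), tuple(n_unvax), tuple(h_vax), tuple(h_unvax))


def _hd_sum(comp: HazardComponents, weights: Sequence[Number]) -> Number:
    return sum(
        w * (hu - hv)
        for w, hu, hv in zip(weights, comp.h_unvax, comp.h_vax)
    )


def unbiased_estimator(
    arm: ArmIncidence,
    strategy: Optional[Strategy] = None,
    n_total: Optional[Number] = None,
) -> Number:
    """Unbiased plug-in estimator from arm-resolved sample incidences.

    Identical arithmetic to :func:`vaxavert.estimands.direct_impact` applied
    to sampled proportions; works for any number of vaccination times.
    """
    return estimands.direct_impact(arm, strategy, n_total).value


def hazard_difference_estimator(table: StatusTable) -> Number:
    """The empirical-study estimator: sum over intervals of vaccinated
    survivors times the (not-yet-vaccinated minus vaccinated) hazard."""
    comp = hazard_components(table)
    return _hd_sum(comp, comp.n_vax)


def avertible_hd_estimator(table: StatusTable) -> Number:
    """Hazard-difference analogue for avertible outcomes: weights are
    not-yet-vaccinated survivors."""
    comp = hazard_components(table)
    return _hd_sum(comp, comp.n_unvax)


def alt_unbiased_estimator(table: StatusTable) -> Number:
    """Estimator of the direct impact from status-aggregated data whose
    randomization expectation equals the estimand.

    Interval 0 contributes the same term as the hazard-difference estimator,
    ``N_v[0] * (h_u[1] - h_v[1])`` (at baseline nobody has been depleted, so
    the term is already unbiased).  For each later interval ``k >= 1`` the
    not-yet-vaccinated hazard is weighted by *unvaccinated* survivors scaled
    by the assignment odds of being vaccinated by ``k``,

        (sum_{x<=k} rho_x / sum_{x>k} rho_x) * N_u[k] * h_u[k+1] - N_v[k] * h_v[k+1],

    which removes the differential-depletion weighting that biases the
    hazard-difference estimator.  Requires a positive never-vaccinated
    assigned proportion (the reweighting is undefined otherwise).

    Note: this equals the arm-resolved :func:`unbiased_estimator` in
    expectation (and on any sample where the not-yet-vaccinated arms share
    identical early incidence, e.g. deterministic population truths), but
    not realization-by-realization — the aggregated table no longer carries
    the arm-resolved early incidences the plug-in uses.
    """
    strategy = table.strategy
    rho = strategy.rho
    comp = hazard_components(table)
    total = comp.n_vax[0] * (comp.h_unvax[0] - comp.h_vax[0])
    for k in range(1, comp.n_intervals):
        rho_vax = sum(rho[x] for x in range(k + 1))
        rho_unvax = sum(rho[x] for x in range(k + 1, strategy.n_arms))
        if rho_unvax == 0:
            raise ZeroDivisionError(
                "alternative unbiased estimator needs a positive not-yet-"
                f"vaccinated assigned proportion at interval {k} "
                "(rho of the never-vaccinated arm is 0)"
            )
        total += (
            exact_div(rho_vax, rho_unvax) * comp.n_unvax[k] * comp.h_unvax[k]
            - comp.n_vax[k] * comp.h_vax[k]
        )
    return total


def _truth_components(
    arm: ArmIncidence, strategy: Strategy, n_total: Number
) -> HazardComponents:
    """Population-truth hazard components: the deterministic (large-sample)
    limit in which sample ratios are replaced by ratios of truths."""
    rho = strategy.rho
    never = strategy.never_label
    n_vax, n_unvax, h_vax, h_unvax = [], [], [], []
    for k in range(strategy.n_times):
        vax_arms = range(k + 1)
        unvax_arms = range(k + 1, strategy.n_arms)
        surv_v = sum(rho[x] * (1 - arm.Y[k][x]) for x in vax_arms)
        surv_u = sum(rho[x] * (1 - arm.Y[k][x]) for x in unvax_arms)
        ev_v = sum(rho[x] * arm.delta(k + 1, x) for x in vax_arms)
        ev_u = sum(rho[x] * arm.delta(k + 1, x) for x in unvax_arms)
        n_vax.append(n_total * surv_v)
        n_unvax.append(n_total * surv_u)
        h_vax.append(_hazard(ev_v, surv_v, f"vaccinated truth, interval {k}"))
        h_unvax.append(_hazard(ev_u, surv_u, f"not-yet-vaccinated truth, interval {k}"))
    return HazardComponents(tuple(n_vax), tuple(n_unvax), tuple(h_vax), tuple(h_unvax))


def hd_expectation(
    arm_truth: ArmIncidence,
    strategy: Optional[Strategy] = None,
    n_total: Optional[Number] = None,
) -> Number:
    """Closed-form expectation of the hazard-difference estimator on
    population-truth incidences.

    Equals the estimand exactly when, at every interval, the assignment-
    weighted survival of the vaccinated arms matches the survival of the
    not-yet-vaccinated arms (in particular under a null vaccine); exceeds it
    when the never-vaccinated arm's survival is lower (depletion of
    susceptibles).  Raises when a positive event mass sits on an exhausted
    risk set (e.g. the never arm fully depleted before the end).
    """
    strategy = strategy if strategy is not None else arm_truth.strategy
    n_total = n_total if n_total is not None else arm_truth.n_total
    comp = _truth_components(arm_truth, strategy, n_total)
    return _hd_sum(comp, comp.n_vax)


def hd_bias(
    arm_truth: ArmIncidence,
    strategy: Optional[Strategy] = None,
    n_total: Optional[Number] = None,
) -> Number:
    """Bias of the hazard-difference estimator: expectation minus estimand."""
    return hd_expectation(arm_truth, strategy, n_total) - estimands.direct_impact(
        arm_truth, strategy, n_total
    ).value


# Convenience record-level wrappers, used by the finite-trial enumeration.

def unbiased_from_records(
    records: Sequence[IndividualRecord], strategy: Strategy
) -> Number:
    return unbiased_estimator(arm_incidence_from_records(records, strategy))


def hd_from_records(
    records: Sequence[IndividualRecord], strategy: Strategy
) -> Number:
    return hazard_difference_estimator(status_table_from_records(records, strategy))


def alt_unbiased_from_records(
    records: Sequence[IndividualRecord], strategy: Strategy
) -> Number:
    return alt_unbiased_estimator(status_table_from_records(records, strategy))


def avertible_hd_from_records(
    records: Sequence[IndividualRecord], strategy: Strategy
) -> Number:
    return avertible_hd_estimator(status_table_from_records(records, strategy))


ESTIMATORS_FROM_RECORDS: dict = {
    "unbiased": unbiased_from_records,
    "hazard-diff": hd_from_records,
    "alt-unbiased": alt_unbiased_from_records,
    "avertible-hd": avertible_hd_from_records,
}
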