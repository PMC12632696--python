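"""Causal estimands for outcomes directly averted by a vaccination rollout.

The *direct impact* of a rollout strategy rho, relative to no vaccination,
is the expected number of outcomes prevented among vaccinated individuals by
their own vaccination, holding the rest of the program (coverage and timing)
fixed:

    delta^D = N * sum_{x=0}^{q} rho_x * [Ybar(never) - Ybar(x)]

where ``Ybar(x)`` is the group-average potential cumulative incidence at the
end of follow-up for individuals assigned vaccination time ``x`` while the
group follows rho.  Each bracket is a *direct effect*: the contrast between
never-vaccinated and vaccinated-at-``x`` individuals under the same program.
When the indirect effect of the program is non-negative, the direct impact
is a lower bound on the *overall impact* — the total outcomes averted in the
whole population relative to a counterfactual with no vaccination at all.

These operations take any :class:`~vaxavert.trial_data.ArmIncidence` table;
applied to population-truth incidences they are estimands, applied to sample
proportions they are the corresponding plug-in estimators (the arithmetic is
shared; see :mod:`vaxavert.estimators`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

from .trial_data import ArmIncidence, Number, Strategy

__all__ = [
    "ImpactResult",
    "direct_effect",
    "direct_impact",
    "overall_impact",
    "avertible_impact",
]


@dataclass(frozen=True)
class ImpactResult:
    """An expected count of averted (or avertible) outcomes.

    ``value`` is on the scale of N (people); ``per_arm_contributions`` maps
    each contributing arm to its ``N * rho_x * DE`` term and sums to
    ``value``.
    """

    value: Number
    per_arm_contributions: Dict[int, Number] = field(default_factory=dict)
    outcome_label: str = "outcome"

    def __post_init__(self):
        if self.per_arm_contributions:
            total = sum(self.per_arm_contributions.values())
            scale = max(1.0, abs(float(self.value)))
            if abs(float(total - self.value)) > 1e-9 * scale:
                raise ValueError(
                    "per-arm contributions do not sum to the impact value"
                )


def _resolve(arm: ArmIncidence, strategy: Optional[Strategy], n_total: Optional[Number]):
    strategy = strategy if strategy is not None else arm.strategy
    n_total = n_total if n_total is not None else arm.n_total
    if strategy.n_arms != len(arm.Y[0]):
        raise ValueError(
            f"strategy has {strategy.n_arms} arms but incidence table has "
            f"{len(arm.Y[0])} columns"
        )
    return strategy, n_total


def direct_effect(arm: ArmIncidence, x_prime: int, l: Optional[int] = None) -> Number:
    """Direct effect: incidence contrast between the never-vaccinated arm and
    arm ``x_prime`` at measurement interval ``l`` (default end of follow-up).

    May be negative (a harmful vaccine).  Undefined for the never arm itself.
    """
    never = arm.strategy.never_label
    if x_prime == never:
        raise ValueError(
            "direct effect contrasts a vaccination time against never-vaccinated; "
            f"x_prime={x_prime} is the never-vaccinated label"
        )
    if not 0 <= x_prime < never:
        raise ValueError(f"x_prime={x_prime} outside 0..{never - 1}")
    l = arm.last if l is None else l
    if not 0 <= l <= arm.last:
        raise ValueError(f"measurement interval l={l} outside 0..{arm.last}")
    return arm.Y[l][never] - arm.Y[l][x_prime]


def direct_impact(
    arm: ArmIncidence,
    strategy: Optional[Strategy] = None,
    n_total: Optional[Number] = None,
    outcome_label: str = "outcome",
) -> ImpactResult:
    """Expected number of outcomes directly averted by the rollout.

    Sums ``N * rho_x * DE(never, x)`` over all vaccination times ``x``; with
    a single vaccination time this reduces to ``N * rho_0 * DE(1, 0)``.
    """
    strategy, n_total = _resolve(arm, strategy, n_total)
    never = strategy.never_label
    contributions = {}
    for x in range(never):
        contributions[x] = n_total * strategy.rho[x] * direct_effect(arm, x)
    return ImpactResult(
        value=sum(contributions.values()),
        per_arm_contributions=contributions,
        outcome_label=outcome_label,
    )


def overall_impact(
    arm_under_rho: ArmIncidence,
    arm_under_phi: ArmIncidence,
    strategy: Optional[Strategy] = None,
    n_total: Optional[Number] = None,
) -> Number:
    """Total outcomes averted in the whole population by the rollout,
    relative to a counterfactual run with no vaccination.

    ``N * (overall incidence under phi - rho-weighted overall incidence
    under rho)`` at the end of follow-up.  When the indirect effect is
    non-negative this is bounded below by :func:`direct_impact`.
    """
    strategy, n_total = _resolve(arm_under_rho, strategy, n_total)
    phi_strategy = arm_under_phi.strategy
    if phi_strategy.n_times != strategy.n_times or (
        phi_strategy.interval_days != strategy.interval_days
    ):
        raise ValueError("counterfactual run is on a different interval grid")
    l = arm_under_rho.last
    inc_rho = sum(
        strategy.rho[x] * arm_under_rho.Y[l][x] for x in range(strategy.n_arms)
    )
    inc_phi = sum(
        phi_strategy.rho[x] * arm_under_phi.Y[l][x] for x in range(phi_strategy.n_arms)
    )
    return n_total * (inc_phi - inc_rho)


def avertible_impact(
    arm: ArmIncidence,
    strategy: Optional[Strategy] = None,
    n_total: Optional[Number] = None,
    counterfactual_time: int = 0,
    outcome_label: str = "outcome",
) -> ImpactResult:
    """Expected outcomes among never-vaccinated individuals that vaccination
    at ``counterfactual_time`` would have prevented.

    ``N * rho_never * (Y(never) - Y(counterfactual_time))`` at the end of
    follow-up.  The counterfactual vaccination time defaults to the earliest
    one and is configurable.
    """
    strategy, n_total = _resolve(arm, strategy, n_total)
    never = strategy.never_label
    if counterfactual_time == never:
        raise ValueError(
            "counterfactual_time must be an actual vaccination time, not the "
            "never-vaccinated label"
        )
    if not 0 <= counterfactual_time < never:
        raise ValueError(f"counterfactual_time={counterfactual_time} outside 0..{never - 1}")
    l = arm.last
    value = n_total * strategy.rho[never] * (
        arm.Y[l][never] - arm.Y[l][counterfactual_time]
    )
    return ImpactResult(
        value=value,
        per_arm_contributions={never: value},
        outcome_label=outcome_label,
    )
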