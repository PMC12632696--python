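"""Exact finite-population machinery for one-stage rollout trials.

A *mixed individual assignment strategy* randomizes a fixed number of
participants to each vaccination time: the assignment vector is a uniformly
random permutation of a fixed type vector.  For desk-scale trials the whole
assignment distribution can be enumerated, so estimator expectations are
exact rational numbers — the independent oracle against which finite-sample
unbiasedness (and the hazard-difference estimator's bias) is checked.

Potential outcomes are generated by a deterministic chain-binomial epidemic:
each participant carries fixed latent uniform thresholds (common random
numbers across counterfactual allocations), and the outcome path under an
allocation is a deterministic function of the allocation — exactly the
potential-outcomes-under-interference setup.  Per-interval infection
probability mirrors the SIRD hazard,

    p_j(l) = 1 - exp(-theta_j(l) * beta * I_l * d / N_alive),

where ``I_l`` counts currently infectious participants, and infection leads
to death with probability ``kappa_j(l) * mu``.  Individuals infected during
one interval are infectious during the next; baseline seeds are infectious
during interval 0 and their own infection is an interval-0 event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from .trial_data import ArmIncidence, IndividualRecord, Strategy

__all__ = [
    "EpiParams",
    "Latents",
    "PotentialOutcomeTable",
    "enumerate_assignments",
    "draw_latents",
    "chain_binomial_outcomes",
    "build_potential_outcomes",
    "group_average_potential_outcome",
    "truth_arm_incidence",
    "exact_expectation",
    "mc_expectation",
    "figure1_fixture",
    "records_from_events",
]

ENUMERATION_GUARD = 10_000


@dataclass(frozen=True)
class EpiParams:
    """Transmission parameters of the desk-scale chain-binomial epidemic.

    Defaults give non-degenerate outcome variety in trials of 4-8 subjects
    with 60-day intervals: a per-interval attack rate of roughly
    ``1 - exp(-0.2)`` per infectious seed, a strongly protective vaccine,
    and a high death probability so both outcomes occur.
    """

    beta: float = 0.02
    mu: float = 0.5
    ve_inf: float = 0.9
    ve_death: float = 0.0
    n_seeds: int = 1

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        for name in ("mu", "ve_inf", "ve_death"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_seeds < 0:
            raise ValueError("n_seeds must be >= 0")


@dataclass(frozen=True)
class Latents:
    """Per-subject uniform thresholds, drawn once and shared across all
    counterfactual allocations (common random numbers)."""

    u_inf: np.ndarray   # (N, n_intervals)
    u_death: np.ndarray  # (N,)
    seed: int


def draw_latents(n_subjects: int, n_intervals: int, seed: int) -> Latents:
    rng = np.random.default_rng(seed)
    return Latents(
        u_inf=rng.random((n_subjects, n_intervals)),
        u_death=rng.random(n_subjects),
        seed=seed,
    )


def enumerate_assignments(strategy: Strategy, n_total: int) -> List[Tuple[int, ...]]:
    """All distinct assignment vectors of the mixed strategy, each equally
    probable.

    Requires every ``rho_x * N`` to be an integer, and refuses to enumerate
    more than ``ENUMERATION_GUARD`` allocations (use :func:`mc_expectation`
    beyond that).
    """
    counts = strategy.arm_counts(n_total)
    n_allocs = math.factorial(n_total)
    for c in counts:
        n_allocs //= math.factorial(c)
    if n_allocs > ENUMERATION_GUARD:
        raise ValueError(
            f"{n_allocs} allocations exceed the enumeration guard "
            f"({ENUMERATION_GUARD}); use the Monte-Carlo expectation instead"
        )
    base = [x for x, c in enumerate(counts) for _ in range(c)]
    return [tuple(p) for p in multiset_permutations(base)]


def _multiplier(l: int, x: int, strategy: Strategy, value: float) -> float:
    """Efficacy multiplier for a subject assigned to ``x`` during interval
    ``l``: in effect from the vaccination interval onward."""
    if x != strategy.never_label and l >= x:
        return value
    return 1.0


def chain_binomial_outcomes(
    latents: Latents,
    allocation: Sequence[int],
    epi: EpiParams,
    strategy: Strategy,
) -> Tuple[Tuple[Optional[int], ...], Tuple[Optional[int], ...]]:
    """Deterministic outcome paths for one allocation.

    Returns ``(infection_events, death_events)``: per subject, the interval
    of the event or ``None``.  Events occur in intervals
    ``0 .. n_times - 1``.
    """
    n = len(allocation)
    n_intervals = strategy.n_times
    d = strategy.interval_days
    theta = 1.0 - epi.ve_inf
    kappa = 1.0 - epi.ve_death

    inf_event: List[Optional[int]] = [None] * n
    death_event: List[Optional[int]] = [None] * n
    dead = [False] * n

    def resolve_death(j: int, l: int) -> None:
        if latents.u_death[j] < _multiplier(l, allocation[j], strategy, kappa) * epi.mu:
            death_event[j] = l
            dead[j] = True

    # Baseline seeds: infected at interval 0, infectious during interval 0.
    infectious = [j for j in range(min(epi.n_seeds, n))]
    for j in infectious:
        inf_event[j] = 0
        resolve_death(j, 0)

    for l in range(n_intervals):
        n_alive = sum(1 for j in range(n) if not dead[j] or death_event[j] == l)
        i_l = len(infectious)
        newly_infected = []
        if i_l > 0 and n_alive > 0:
            for j in range(n):
                if inf_event[j] is not None or dead[j]:
                    continue
                th = _multiplier(l, allocation[j], strategy, theta)
                p = 1.0 - math.exp(-th * epi.beta * i_l * d / n_alive)
                if latents.u_inf[j, l] < p:
                    inf_event[j] = l
                    resolve_death(j, l)
                    newly_infected.append(j)
        # Those infected during l transmit during l + 1, unless they died.
        infectious = [j for j in newly_infected if not dead[j]]

    return tuple(inf_event), tuple(death_event)


@dataclass(frozen=True)
class PotentialOutcomeTable:
    """Potential outcome paths for every allocation in the support of a
    mixed strategy, generated from one shared set of latents."""

    strategy: Strategy
    n_total: int
    allocations: tuple
    paths: Dict[tuple, tuple] = field(repr=False)  # alloc -> (inf_events, death_events)
    latents: Optional[Latents] = field(default=None, repr=False, compare=False)

    @property
    def weight(self) -> Fraction:
        """Probability of each allocation (uniform over the support)."""
        return Fraction(1, len(self.allocations))

    def event_intervals(self, allocation: tuple, outcome: str) -> tuple:
        inf, death = self.paths[allocation]
        if outcome == "infection":
            return inf
        if outcome == "death":
            return death
        raise ValueError(f"outcome must be 'infection' or 'death', got {outcome!r}")

    def cumulative(self, l: int, j: int, allocation: tuple, outcome: str = "infection") -> int:
        """Cumulative 0/1 outcome indicator before the beginning of interval l."""
        ev = self.event_intervals(allocation, outcome)[j]
        return int(ev is not None and ev < l)

    def records(self, allocation: tuple, outcome: str = "infection") -> List[IndividualRecord]:
        events = self.event_intervals(allocation, outcome)
        return records_from_events(allocation, events)


def records_from_events(
    allocation: Sequence[int], events: Sequence[Optional[int]]
) -> List[IndividualRecord]:
    return [
        IndividualRecord(id=str(j), assigned_time=x, event_interval=ev)
        for j, (x, ev) in enumerate(zip(allocation, events))
    ]


def build_potential_outcomes(
    strategy: Strategy,
    n_total: int,
    epi: Optional[EpiParams] = None,
    seed: int = 0,
) -> PotentialOutcomeTable:
    """Enumerate all allocations and realize the chain-binomial outcome path
    of each one from a single latent draw."""
    epi = epi if epi is not None else EpiParams()
    allocations = enumerate_assignments(strategy, n_total)
    latents = draw_latents(n_total, strategy.n_times, seed)
    paths = {
        alloc: chain_binomial_outcomes(latents, alloc, epi, strategy)
        for alloc in allocations
    }
    return PotentialOutcomeTable(
        strategy=strategy,
        n_total=n_total,
        allocations=tuple(allocations),
        paths=paths,
        latents=latents,
    )


def group_average_potential_outcome(
    pot: PotentialOutcomeTable,
    x: int,
    l: int,
    outcome: str = "infection",
) -> Fraction:
    """Group-average potential outcome Ybar_l(x): the allocation-weighted
    average cumulative incidence among subjects assigned to ``x``."""
    if pot.strategy.rho[x] == 0:
        raise ValueError(
            f"group average undefined for arm {x}: assigned proportion is 0"
        )
    total = Fraction(0)
    for alloc in pot.allocations:
        members = [j for j, a in enumerate(alloc) if a == x]
        total += Fraction(
            sum(pot.cumulative(l, j, alloc, outcome) for j in members), len(members)
        )
    return total * pot.weight


def truth_arm_incidence(
    pot: PotentialOutcomeTable, outcome: str = "infection"
) -> ArmIncidence:
    """Population-truth incidence table of group averages (the estimand
    substrate), exact in rational arithmetic."""
    s = pot.strategy
    rows = []
    for l in range(s.n_times + 1):
        rows.append(
            tuple(
                group_average_potential_outcome(pot, x, l, outcome)
                if s.rho[x] > 0
                else Fraction(0)
                for x in range(s.n_arms)
            )
        )
    return ArmIncidence(rows, pot.n_total, s)


def exact_expectation(
    estimator: Callable[[Sequence[IndividualRecord], Strategy], object],
    pot: PotentialOutcomeTable,
    outcome: str = "infection",
) -> Fraction:
    """Exact randomization expectation of an estimator: the probability-
    weighted average of its value on the observed data of each allocation.

    ``estimator`` takes ``(records, strategy)`` — see the
    ``*_from_records`` wrappers in :mod:`vaxavert.estimators`.
    """
    total = Fraction(0)
    for alloc in pot.allocations:
        try:
            value = estimator(pot.records(alloc, outcome), pot.strategy)
        except Exception as exc:
            raise RuntimeError(
                f"estimator failed on allocation {alloc}: {exc}"
            ) from exc
        total += Fraction(value)
    return total * pot.weight


def mc_expectation(
    estimator: Callable[[Sequence[IndividualRecord], Strategy], object],
    strategy: Strategy,
    n_total: int,
    epi: Optional[EpiParams] = None,
    seed: int = 0,
    n_draws: int = 1000,
    outcome: str = "infection",
    latents: Optional[Latents] = None,
) -> Tuple[float, float]:
    """Monte-Carlo estimator expectation for trials too large to enumerate.

    Draws random permutations of the type vector (latents stay fixed, and
    can be supplied to target a specific potential-outcome table) and
    returns ``(mean, standard error)``.
    """
    epi = epi if epi is not None else EpiParams()
    counts = strategy.arm_counts(n_total)
    base = np.array([x for x, c in enumerate(counts) for _ in range(c)])
    rng = np.random.default_rng(seed)
    if latents is None:
        latents = draw_latents(n_total, strategy.n_times, seed + 1)
    values = []
    for _ in range(n_draws):
        alloc = tuple(int(v) for v in rng.permutation(base))
        events = chain_binomial_outcomes(latents, alloc, epi, strategy)
        ev = events[0] if outcome == "infection" else events[1]
        values.append(float(estimator(records_from_events(alloc, ev), strategy)))
    arr = np.asarray(values)
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(n_draws))


def figure1_fixture() -> Tuple[List[IndividualRecord], Strategy, int]:
    """The six-person worked-example trial: two vaccination times, 60-day
    intervals, one third of subjects per arm.

    Arm 0 (vaccinated at baseline): no events.  Arm 1 (vaccinated at
    interval 1): one event during interval 0, one subject event-free.
    Arm 2 (never vaccinated): one event during interval 0 and one during
    interval 1.  Arm cumulative incidences at the end of follow-up are
    0, 1/2 and 1; the unbiased estimator gives 3 averted outcomes and the
    hazard-difference estimator gives 4.
    """
    strategy = Strategy(2, 60, (Fraction(1, 3), Fraction(1, 3), Fraction(1, 3)))
    records = [
        IndividualRecord("s1", 0, None),
        IndividualRecord("s2", 0, None),
        IndividualRecord("s3", 1, 0),
        IndividualRecord("s4", 1, None),
        IndividualRecord("s5", 2, 0),
        IndividualRecord("s6", 2, 1),
    ]
    return records, strategy, 6
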