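"""Stratified susceptible-infected-recovered-death (SIRD) simulator.

The population is divided into strata by assigned vaccination time ``x``
(including a never-vaccinated stratum).  Within each stratum the dynamics
are the standard SIRD system; vaccination multiplies the stratum's infection
hazard by ``theta = 1 - VE_inf`` and its death-given-infection probability
by ``kappa = 1 - VE_death`` from the stratum's vaccination day onward (the
multipliers are time-varying for strata vaccinated after baseline; the
never-vaccinated stratum always has multiplier 1).  The force of infection

    lambda(t) = beta * sum_x I_x(t) / N(t),      N(t) = total alive,

is shared across strata, which is how vaccination of one stratum indirectly
protects the others.

The continuous system is advanced by forward Euler in day steps (with an
optional sub-stepping factor to guard positivity for fast epidemics), and
state is tracked as per-capita fractions of each stratum.  Tracking
fractions makes strata with identical parameters follow bit-identical
trajectories, so null contrasts (e.g. zero vaccine efficacy against
infection) yield exactly zero averted infections rather than float dust.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .trial_data import ArmIncidence, Strategy

__all__ = [
    "SirdParams",
    "Trajectory",
    "simulate",
    "extract_arm_incidence",
    "basic_reproduction_number",
]


@dataclass(frozen=True)
class SirdParams:
    """Parameters of the stratified SIRD model.

    beta:
        Effective contacts per infectious individual per day.
    gamma:
        Recovery (outflow) rate per day; 1/gamma is the mean infectious
        period.
    mu:
        Probability of death given infection (the IFR).
    ve_inf:
        Vaccine efficacy against infection; the infection-hazard multiplier
        is ``theta = 1 - ve_inf``.
    ve_death:
        Vaccine efficacy against death given infection; the death multiplier
        is ``kappa = 1 - ve_death``.
    strategy:
        Rollout law; stratum ``x`` is vaccinated on day
        ``x * interval_days``.
    n0, i0:
        Initial population and initial infectious count; ``i0`` is seeded
        proportionally across strata at t=0, the remainder susceptible.
    horizon_days:
        Simulation length; defaults to the full measurement grid
        ``n_times * interval_days``.
    substeps:
        Euler sub-steps per day (>= 1).
    """

    beta: float
    gamma: float
    mu: float
    ve_inf: float
    ve_death: float
    strategy: Strategy
    n0: float = 1_000_000
    i0: float = 1_000
    horizon_days: Optional[int] = None
    substeps: int = 1

    def __post_init__(self):
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("rates beta and gamma must be non-negative")
        for name in ("mu", "ve_inf", "ve_death"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.i0 < 0 or self.i0 > self.n0:
            raise ValueError("need 0 <= i0 <= n0")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if self.horizon_days is not None and self.horizon_days < self.grid_days:
            raise ValueError(
                f"horizon_days={self.horizon_days} shorter than the measurement "
                f"grid ({self.grid_days} days)"
            )

    @property
    def grid_days(self) -> int:
        return self.strategy.n_times * self.strategy.interval_days

    @property
    def horizon(self) -> int:
        return self.grid_days if self.horizon_days is None else int(self.horizon_days)

    @property
    def theta(self) -> float:
        return 1.0 - self.ve_inf

    @property
    def kappa(self) -> float:
        return 1.0 - self.ve_death


def basic_reproduction_number(params: SirdParams) -> float:
    """R0 = beta / gamma for this model."""
    if params.gamma == 0:
        raise ZeroDivisionError("R0 undefined for gamma = 0")
    return params.beta / params.gamma


@dataclass(frozen=True)
class Trajectory:
    """Daily per-stratum state, stored as fractions of each stratum.

    ``s``, ``i``, ``r``, ``d`` have shape ``(horizon + 1, n_arms)``;
    ``sizes`` are the stratum populations ``rho_x * n0``.  Absolute counts
    are ``frac * sizes``.
    """

    params: SirdParams
    days: np.ndarray
    s: np.ndarray
    i: np.ndarray
    r: np.ndarray
    d: np.ndarray
    sizes: np.ndarray = field(repr=False)

    def conservation_error(self) -> float:
        """Largest absolute-count violation of S+I+R+D = stratum size."""
        total = self.s + self.i + self.r + self.d
        return float(np.max(np.abs(total - 1.0) * np.maximum(self.sizes, 1.0)))

    def cumulative_infection_fraction(self, day: int) -> np.ndarray:
        """Per-stratum fraction infected after baseline, by ``day``."""
        return self.s[0] - self.s[day]

    def cumulative_death_fraction(self, day: int) -> np.ndarray:
        return self.d[day]

    def to_frame(self) -> pd.DataFrame:
        """Tidy daily table of absolute compartment counts."""
        n_days, n_arms = self.s.shape
        rows = []
        for x in range(n_arms):
            size = self.sizes[x]
            rows.append(
                pd.DataFrame(
                    {
                        "day": self.days,
                        "stratum": x,
                        "S": self.s[:, x] * size,
                        "I": self.i[:, x] * size,
                        "R": self.r[:, x] * size,
                        "D": self.d[:, x] * size,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def simulate(params: SirdParams) -> Trajectory:
    """Advance the stratified SIRD system by forward Euler day steps."""
    strat = params.strategy
    n_arms = strat.n_arms
    never = strat.never_label
    sizes = np.array([float(r) * params.n0 for r in strat.rho])
    horizon = params.horizon

    # Per-capita seeding is identical across strata by construction.
    i_seed = params.i0 / params.n0
    s_cur = np.full(n_arms, 1.0 - i_seed)
    i_cur = np.full(n_arms, i_seed)
    r_cur = np.zeros(n_arms)
    d_cur = np.zeros(n_arms)

    vacc_day = np.array(
        [strat.vaccination_day(x) if x != never else np.inf for x in range(n_arms)],
        dtype=float,
    )

    shape = (horizon + 1, n_arms)
    s = np.empty(shape)
    i = np.empty(shape)
    r = np.empty(shape)
    d = np.empty(shape)
    s[0], i[0], r[0], d[0] = s_cur, i_cur, r_cur, d_cur

    dt = 1.0 / params.substeps
    for day in range(horizon):
        for sub in range(params.substeps):
            t = day + sub * dt
            vaccinated = t >= vacc_day
            theta_t = np.where(vaccinated, params.theta, 1.0)
            kappa_t = np.where(vaccinated, params.kappa, 1.0)
            alive = sizes @ (1.0 - d_cur)
            lam = params.beta * (sizes @ i_cur) / alive if alive > 0 else 0.0
            new_inf = theta_t * lam * s_cur * dt
            resolved = params.gamma * i_cur * dt
            s_cur = s_cur - new_inf
            i_cur = i_cur + new_inf - resolved
            r_cur = r_cur + (1.0 - kappa_t * params.mu) * resolved
            d_cur = d_cur + kappa_t * params.mu * resolved
            if np.min(s_cur) < -1e-12 or np.min(i_cur) < -1e-12:
                raise FloatingPointError(
                    f"Euler step at day {t:g} drove a compartment negative; "
                    "reduce beta or increase SirdParams.substeps"
                )
            s_cur = np.maximum(s_cur, 0.0)
            i_cur = np.maximum(i_cur, 0.0)
        s[day + 1], i[day + 1], r[day + 1], d[day + 1] = s_cur, i_cur, r_cur, d_cur

    return Trajectory(
        params=params,
        days=np.arange(horizon + 1),
        s=s, i=i, r=r, d=d,
        sizes=sizes,
    )


def extract_arm_incidence(
    traj: Trajectory,
    outcome: str,
    strategy: Optional[Strategy] = None,
) -> ArmIncidence:
    """Population-truth cumulative incidence per stratum on the measurement
    grid (days ``0, d, 2d, ...``).

    ``outcome`` is ``"infection"`` (fraction of the stratum leaving S after
    baseline) or ``"death"`` (fraction of the stratum in D).
    """
    if outcome not in ("infection", "death"):
        raise ValueError(f"outcome must be 'infection' or 'death', got {outcome!r}")
    strategy = strategy if strategy is not None else traj.params.strategy
    d = strategy.interval_days
    horizon = traj.s.shape[0] - 1
    if strategy.n_times * d > horizon:
        raise ValueError(
            f"trajectory covers {horizon} days but the measurement grid needs "
            f"{strategy.n_times * d}"
        )
    rows = []
    for l in range(strategy.n_times + 1):
        day = l * d
        if outcome == "infection":
            frac = traj.cumulative_infection_fraction(day)
        else:
            frac = traj.cumulative_death_fraction(day)
        rows.append(tuple(frac))
    return ArmIncidence(rows, traj.params.n0, strategy)
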