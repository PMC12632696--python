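"""Domain types and I/O for staggered-rollout trial and surveillance data.

A rollout *strategy* assigns each of ``N`` trial participants a vaccination
time ``x`` drawn from ``{0, ..., n_times}``: vaccination at the beginning of
interval ``x`` for ``x < n_times``, or never vaccinated (``x == n_times``).
Follow-up is divided into ``n_times`` evenly spaced intervals of
``interval_days`` days each; interval ``l`` opens on day ``l * interval_days``
and measurements are taken at the instant each interval opens, so cumulative
incidence ``Y[l][x]`` is the fraction of arm ``x`` that experienced the
outcome strictly before interval ``l`` opened.  ``Y[0][x] == 0`` by
convention.  Events on a vaccination day count as post-vaccination.

Two data shapes are supported:

* arm-resolved data (:class:`IndividualRecord` rows, or the
  :class:`ArmIncidence` table built from them) — what an ideal trial yields;
* status-aggregated data (:class:`StatusTable`) — survivors and events among
  *currently vaccinated* versus *not-yet-vaccinated* individuals per
  interval, the shape most surveillance registries publish.  Each row pairs
  the numbers at risk at the beginning of interval ``k`` with the events of
  interval ``k`` (i.e. the hazard one interval ahead of the survivors).

Arithmetic is type-generic: counts are integers, proportions may be exact
:class:`fractions.Fraction` values (small trials, enumeration oracles) or
floats (simulation-scale inputs), and every derived quantity preserves
exactness when the inputs are exact.
"""

from __future__ import annotations

import csv
import numbers
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

Number = Union[int, float, Fraction]

__all__ = [
    "Strategy",
    "IndividualRecord",
    "ArmIncidence",
    "StatusRow",
    "StatusTable",
    "arm_incidence_from_records",
    "status_table_from_records",
    "read_status_table",
    "write_status_table",
    "read_records",
    "write_records",
    "exact_div",
]


def exact_div(num: Number, den: Number) -> Number:
    """Divide, returning an exact Fraction whenever both operands are exact."""
    if isinstance(num, (int, Fraction)) and isinstance(den, (int, Fraction)):
        return Fraction(num, den) if isinstance(den, int) else Fraction(num) / den
    return num / den


def _is_number(v: object) -> bool:
    return isinstance(v, numbers.Real)


@dataclass(frozen=True)
class Strategy:
    """A rollout law: how many vaccination times, how long each interval is,
    and which fraction of the population is assigned to each time.

    Parameters
    ----------
    n_times:
        Number of potential vaccination times (``>= 1``).  Arm labels run
        over ``{0, ..., n_times}`` with ``n_times`` meaning never vaccinated.
    interval_days:
        Length ``d`` of each follow-up interval, in days.
    rho:
        Assignment proportions ``(rho_0, ..., rho_{n_times})``; the last
        entry is the never-vaccinated fraction.  Must be non-negative and
        sum to 1 (within 1e-12).
    """

    n_times: int
    interval_days: int
    rho: tuple

    def __init__(self, n_times: int, interval_days: int, rho: Sequence[Number]):
        object.__setattr__(self, "n_times", int(n_times))
        object.__setattr__(self, "interval_days", int(interval_days))
        object.__setattr__(self, "rho", tuple(rho))
        self._validate()

    def _validate(self) -> None:
        if self.n_times < 1:
            raise ValueError(f"n_times must be >= 1, got {self.n_times}")
        if self.interval_days <= 0:
            raise ValueError(f"interval_days must be positive, got {self.interval_days}")
        if len(self.rho) != self.n_times + 1:
            raise ValueError(
                f"rho must have length n_times + 1 = {self.n_times + 1}, "
                f"got {len(self.rho)}"
            )
        if any((not _is_number(r)) or r < 0 for r in self.rho):
            raise ValueError(f"assignment proportions must be >= 0, got {self.rho}")
        total = sum(self.rho)
        if abs(total - 1) > 1e-12:
            raise ValueError(f"assignment proportions must sum to 1, got {total!r}")

    @property
    def never_label(self) -> int:
        """Arm label of the never-vaccinated group."""
        return self.n_times

    @property
    def n_arms(self) -> int:
        return self.n_times + 1

    @property
    def rho_never(self) -> Number:
        return self.rho[self.never_label]

    def vaccination_day(self, x: int) -> Optional[int]:
        """Day on which arm ``x`` is vaccinated, or None for the never arm."""
        if x == self.never_label:
            return None
        return x * self.interval_days

    @classmethod
    def no_vaccination(cls, n_times: int, interval_days: int) -> "Strategy":
        """The counterfactual strategy assigning everyone to never-vaccinated."""
        rho = (0,) * n_times + (1,)
        return cls(n_times, interval_days, rho)

    def arm_counts(self, n_total: int, *, tol: float = 1e-9) -> tuple:
        """Exact integer arm sizes ``rho_x * n_total``.

        Raises ``ValueError`` when any product is not an integer (adjust
        ``n_total`` so that every ``rho_x * n_total`` is whole).
        """
        counts = []
        for x, r in enumerate(self.rho):
            c = r * n_total
            rounded = round(c)
            if abs(c - rounded) > tol:
                raise ValueError(
                    f"rho[{x}] * N = {c!r} is not an integer; choose N so that "
                    "every arm size is whole"
                )
            counts.append(int(rounded))
        if sum(counts) != n_total:
            raise ValueError(
                f"arm counts {counts} do not sum to N={n_total}; adjust N or rho"
            )
        return tuple(counts)


@dataclass(frozen=True)
class IndividualRecord:
    """One trial participant: assigned vaccination time and outcome interval.

    ``event_interval`` is the follow-up interval during which the outcome
    occurred (an event in interval ``l`` contributes to the incidence
    increment between measurements ``l`` and ``l + 1``), or ``None`` if the
    participant finished follow-up event-free.
    """

    id: str
    assigned_time: int
    event_interval: Optional[int] = None

    def validate(self, strategy: Strategy) -> None:
        if not 0 <= self.assigned_time <= strategy.never_label:
            raise ValueError(
                f"record {self.id!r}: assigned_time {self.assigned_time} outside "
                f"0..{strategy.never_label}"
            )
        if self.event_interval is not None and not (
            0 <= self.event_interval <= strategy.n_times
        ):
            raise ValueError(
                f"record {self.id!r}: event_interval {self.event_interval} outside "
                f"0..{strategy.n_times}"
            )

    def event_before(self, l: int) -> bool:
        """Did the outcome occur before the beginning of interval ``l``?"""
        return self.event_interval is not None and self.event_interval < l


@dataclass(frozen=True)
class ArmIncidence:
    """Cumulative incidence by arm: ``Y[l][x]`` is the fraction of arm ``x``
    with the outcome before the beginning of interval ``l``.

    Rows run over measurement intervals ``l in {0, ..., n_times}``, columns
    over assigned vaccination times ``x in {0, ..., n_times}``.  The same
    container holds sample proportions (an estimator input) and
    population-truth proportions (an estimand input); the arithmetic is
    identical and the caller keeps track of which is which.
    """

    Y: tuple  # tuple of rows, each a tuple over arms
    n_total: Number
    strategy: Strategy
    _float_tol: float = field(default=1e-9, repr=False, compare=False)

    def __init__(self, Y, n_total, strategy, _float_tol: float = 1e-9):
        object.__setattr__(self, "Y", tuple(tuple(row) for row in Y))
        object.__setattr__(self, "n_total", n_total)
        object.__setattr__(self, "strategy", strategy)
        object.__setattr__(self, "_float_tol", _float_tol)
        self._validate()

    def _validate(self) -> None:
        s = self.strategy
        if len(self.Y) != s.n_times + 1:
            raise ValueError(
                f"incidence table needs {s.n_times + 1} rows (intervals), got {len(self.Y)}"
            )
        tol = self._float_tol
        for l, row in enumerate(self.Y):
            if len(row) != s.n_arms:
                raise ValueError(
                    f"row {l} has {len(row)} arms, strategy has {s.n_arms}"
                )
            for x, v in enumerate(row):
                if v < -tol or v > 1 + tol:
                    raise ValueError(f"Y[{l}][{x}] = {v!r} outside [0, 1]")
                if l == 0 and abs(v) > tol:
                    raise ValueError(f"Y[0][{x}] must be 0, got {v!r}")
                if l > 0 and v < self.Y[l - 1][x] - tol:
                    raise ValueError(
                        f"cumulative incidence must be non-decreasing: "
                        f"Y[{l}][{x}] = {v!r} < Y[{l - 1}][{x}] = {self.Y[l - 1][x]!r}"
                    )

    def delta(self, l: int, x: int) -> Number:
        """Incidence increment between measurements ``l - 1`` and ``l``."""
        if l < 1:
            raise ValueError("delta is defined for l >= 1")
        return self.Y[l][x] - self.Y[l - 1][x]

    @property
    def last(self) -> int:
        """Final measurement interval (end of follow-up)."""
        return self.strategy.n_times


@dataclass(frozen=True)
class StatusRow:
    """One interval of a vaccination-status-aggregated table.

    ``vax_at_risk`` / ``unvax_at_risk`` are survivors at the *beginning* of
    interval ``k`` among currently-vaccinated / not-yet-vaccinated
    individuals; ``vax_events`` / ``unvax_events`` occur *during* interval
    ``k``.  ``crossover_in`` documents how many not-yet-vaccinated survivors
    moved into the vaccinated group at the instant interval ``k`` opened
    (the arm vaccinated at time ``k``); it is optional bookkeeping that makes
    group-wise conservation checkable.
    """

    interval: int
    vax_at_risk: Number
    vax_events: Number
    unvax_at_risk: Number
    unvax_events: Number
    crossover_in: Optional[Number] = None


@dataclass(frozen=True)
class StatusTable:
    """Per-interval survivors and events aggregated by vaccination status."""

    rows: tuple
    n_total: Number
    strategy: Strategy

    def __init__(self, rows: Iterable[StatusRow], n_total: Number, strategy: Strategy):
        object.__setattr__(self, "rows", tuple(rows))
        object.__setattr__(self, "n_total", n_total)
        object.__setattr__(self, "strategy", strategy)
        self._validate()

    def _validate(self) -> None:
        s = self.strategy
        if len(self.rows) != s.n_times:
            raise ValueError(
                f"status table needs {s.n_times} rows (one per interval 0..q), "
                f"got {len(self.rows)}"
            )
        for i, row in enumerate(self.rows):
            if row.interval != i:
                raise ValueError(f"row {i} labelled interval {row.interval}")
            for name in ("vax_at_risk", "vax_events", "unvax_at_risk", "unvax_events"):
                if getattr(row, name) < 0:
                    raise ValueError(f"row {i}: {name} is negative")
            if row.vax_events > row.vax_at_risk:
                raise ValueError(
                    f"row {i}: vax_events ({row.vax_events}) exceed "
                    f"vax_at_risk ({row.vax_at_risk})"
                )
            if row.unvax_events > row.unvax_at_risk:
                raise ValueError(
                    f"row {i}: unvax_events ({row.unvax_events}) exceed "
                    f"unvax_at_risk ({row.unvax_at_risk})"
                )
        # Conservation across consecutive rows: survivors only leave a status
        # group through an event or (for the unvaccinated) through crossover.
        for i in range(len(self.rows) - 1):
            a, b = self.rows[i], self.rows[i + 1]
            tot_a = a.vax_at_risk + a.unvax_at_risk
            ev_a = a.vax_events + a.unvax_events
            tot_b = b.vax_at_risk + b.unvax_at_risk
            if abs(tot_b - (tot_a - ev_a)) > 1e-9:
                raise ValueError(
                    f"rows {i}->{i + 1}: at-risk totals not conserved "
                    f"({tot_a} - {ev_a} events != {tot_b})"
                )
            if b.crossover_in is not None:
                if abs(b.vax_at_risk - (a.vax_at_risk - a.vax_events + b.crossover_in)) > 1e-9:
                    raise ValueError(
                        f"row {i + 1}: vaccinated at-risk inconsistent with "
                        f"crossover_in={b.crossover_in}"
                    )

    def row(self, k: int) -> StatusRow:
        return self.rows[k]


def arm_incidence_from_records(
    records: Sequence[IndividualRecord], strategy: Strategy
) -> ArmIncidence:
    """Arm-level cumulative incidence table from individual trial records.

    ``Y[l][x]`` is the fraction of arm-``x`` participants whose event
    occurred before interval ``l`` opened.  Every arm with positive assigned
    proportion must contain at least one record.
    """
    for rec in records:
        rec.validate(strategy)
    n_arms = strategy.n_arms
    by_arm: list = [[] for _ in range(n_arms)]
    for rec in records:
        by_arm[rec.assigned_time].append(rec)
    for x in range(n_arms):
        if strategy.rho[x] > 0 and not by_arm[x]:
            raise ValueError(
                f"arm {x} has assigned proportion {strategy.rho[x]!r} but no records"
            )
    rows = []
    for l in range(strategy.n_times + 1):
        row = []
        for x in range(n_arms):
            arm = by_arm[x]
            if not arm:
                row.append(Fraction(0))
            else:
                row.append(
                    Fraction(sum(1 for r in arm if r.event_before(l)), len(arm))
                )
        rows.append(row)
    return ArmIncidence(rows, len(records), strategy)


def status_table_from_records(
    records: Sequence[IndividualRecord], strategy: Strategy
) -> StatusTable:
    """Aggregate individual records into the vaccination-status table.

    Arm ``x`` counts as vaccinated from interval ``x`` onward (vaccination
    happens at the instant interval ``x`` opens).  At-risk counts are
    survivors-from-the-outcome at the beginning of each interval.
    """
    for rec in records:
        rec.validate(strategy)
    rows = []
    for k in range(strategy.n_times):
        vax_risk = vax_ev = unvax_risk = unvax_ev = 0
        crossover = 0
        for rec in records:
            alive = not rec.event_before(k)
            vaccinated = rec.assigned_time <= k
            if alive:
                if vaccinated:
                    vax_risk += 1
                    if rec.assigned_time == k:
                        crossover += 1
                else:
                    unvax_risk += 1
            if rec.event_interval == k:
                if vaccinated:
                    vax_ev += 1
                else:
                    unvax_ev += 1
        rows.append(
            StatusRow(
                interval=k,
                vax_at_risk=vax_risk,
                vax_events=vax_ev,
                unvax_at_risk=unvax_risk,
                unvax_events=unvax_ev,
                crossover_in=crossover if k > 0 else None,
            )
        )
    return StatusTable(rows, len(records), strategy)


# ---------------------------------------------------------------------------
# CSV plumbing.  Metadata travel as leading '#'-prefixed key=value lines;
# proportions are serialized as exact fractions ("1/3") or decimal strings.

_STATUS_COLUMNS = ["interval", "vax_at_risk", "vax_events", "unvax_at_risk", "unvax_events"]


def _parse_number(text: str) -> Number:
    text = text.strip()
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return Fraction(text)
    except ValueError as exc:
        raise ValueError(f"cannot parse number from {text!r}") from exc


def _read_metadata(path: Path) -> tuple:
    meta = {}
    body = []
    with open(path, newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    meta[key.strip()] = value.strip()
            elif line.strip():
                body.append(line)
    return meta, body


def _strategy_from_meta(meta: dict, path: Path) -> tuple:
    for key in ("n_total", "interval_days", "rho"):
        if key not in meta:
            raise ValueError(f"{path}: missing metadata line '# {key}=...'")
    rho = tuple(_parse_number(tok) for tok in meta["rho"].split(","))
    strategy = Strategy(len(rho) - 1, int(meta["interval_days"]), rho)
    return int(meta["n_total"]), strategy


def _provenance_lines(provenance: Optional[dict]) -> list:
    if not provenance:
        return []
    return [f"# {k}={v}" for k, v in provenance.items()]


def write_status_table(
    table: StatusTable, path: Union[str, Path], provenance: Optional[dict] = None
) -> None:
    """Write a status table as CSV with '#'-prefixed metadata lines."""
    path = Path(path)
    has_crossover = any(r.crossover_in is not None for r in table.rows)
    cols = _STATUS_COLUMNS + (["crossover_in"] if has_crossover else [])
    with open(path, "w", newline="") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        fh.write(f"# n_total={table.n_total}\n")
        fh.write(f"# interval_days={table.strategy.interval_days}\n")
        fh.write(f"# rho={','.join(str(r) for r in table.strategy.rho)}\n")
        writer = csv.writer(fh)
        writer.writerow(cols)
        for row in table.rows:
            out = [row.interval, row.vax_at_risk, row.vax_events,
                   row.unvax_at_risk, row.unvax_events]
            if has_crossover:
                out.append("" if row.crossover_in is None else row.crossover_in)
            writer.writerow(out)


def read_status_table(path: Union[str, Path]) -> StatusTable:
    """Read a status table CSV written by :func:`write_status_table`."""
    path = Path(path)
    meta, body = _read_metadata(path)
    n_total, strategy = _strategy_from_meta(meta, path)
    reader = csv.DictReader(body)
    missing = set(_STATUS_COLUMNS) - set(reader.fieldnames or [])
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for lineno, rec in enumerate(reader):
        try:
            crossover = rec.get("crossover_in")
            row = StatusRow(
                interval=int(rec["interval"]),
                vax_at_risk=_parse_number(rec["vax_at_risk"]),
                vax_events=_parse_number(rec["vax_events"]),
                unvax_at_risk=_parse_number(rec["unvax_at_risk"]),
                unvax_events=_parse_number(rec["unvax_events"]),
                crossover_in=_parse_number(crossover) if crossover else None,
            )
        except ValueError as exc:
            raise ValueError(f"{path}, data row {lineno}: {exc}") from exc
        rows.append(row)
    try:
        return StatusTable(rows, n_total, strategy)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_records(
    records: Sequence[IndividualRecord],
    strategy: Strategy,
    path: Union[str, Path],
    provenance: Optional[dict] = None,
) -> None:
    """Write individual records as CSV (empty event_interval = no event)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        fh.write(f"# n_total={len(records)}\n")
        fh.write(f"# interval_days={strategy.interval_days}\n")
        fh.write(f"# rho={','.join(str(r) for r in strategy.rho)}\n")
        writer = csv.writer(fh)
        writer.writerow(["id", "assigned_time", "event_interval"])
        for rec in records:
            writer.writerow(
                [rec.id, rec.assigned_time,
                 "" if rec.event_interval is None else rec.event_interval]
            )


def read_records(path: Union[str, Path]) -> tuple:
    """Read individual records; returns ``(records, strategy)``."""
    path = Path(path)
    meta, body = _read_metadata(path)
    n_total, strategy = _strategy_from_meta(meta, path)
    reader = csv.DictReader(body)
    missing = {"id", "assigned_time", "event_interval"} - set(reader.fieldnames or [])
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for lineno, rec in enumerate(reader):
        ev = rec["event_interval"].strip()
        record = IndividualRecord(
            id=rec["id"],
            assigned_time=int(rec["assigned_time"]),
            event_interval=int(ev) if ev else None,
        )
        try:
            record.validate(strategy)
        except ValueError as exc:
            raise ValueError(f"{path}, data row {lineno}: {exc}") from exc
        records.append(record)
    if len(records) != n_total:
        raise ValueError(
            f"{path}: metadata n_total={n_total} but {len(records)} rows present"
        )
    return records, strategy
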