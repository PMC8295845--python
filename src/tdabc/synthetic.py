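"""Seeded random scenarios with generator-side ground truth, and a
Monte-Carlo sweep over step-timing uncertainty.

The generator emulates the structure the costing model assumes — timed
steps priced by capacity cost rates, one-time capital with linear
write-off, interval-based consumables and per-patient services — with
magnitudes typical of radiotherapy departments (scanners in the
10^5-10^6 currency range, salaries in the 10^4-10^5 range, step times of
minutes to an hour).  While drawing each item it independently
accumulates the fixed-annual and per-patient sums into a
:class:`GroundTruth`, before any engine code runs, so engine totals can
be checked against an account kept outside the engine.

All randomness flows from a single integer seed; the same seed yields
the same scenario, byte-for-byte when serialized.  Monetary draws are
whole cents, so generated scenarios stay exact rationals.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np

from .engine import capacity_cost_rate, step_cost_per_patient, total_horizon_cost
from .model import (
    CapitalItem,
    Horizon,
    PurchasedService,
    RecurringCost,
    Resource,
    Scenario,
    WorkflowStep,
    as_rational,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_scenario",
    "StochasticSummary",
    "stochastic_cost_sweep",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape and magnitude of generated scenarios.

    Ranges are inclusive (currency per year, currency, or minutes);
    ``p_direct_cost`` is the chance a step carries a direct per-patient
    cost instead of timed work, ``p_per_patient_recurring`` the chance a
    recurring cost scales with volume.
    """

    seed: int = 0
    n_resources: int = 3
    n_steps: int = 4
    n_capital: int = 2
    n_recurring: int = 2
    n_services: int = 1
    salary_range: tuple[int, int] = (40_000, 120_000)  # currency/year
    working_time_range: tuple[int, int] = (80_000, 120_000)  # minutes/year
    capital_range: tuple[int, int] = (50_000, 2_000_000)
    writeoff_choices: tuple[int, ...] = (5, 10, 15, 20)  # years
    recurring_range: tuple[int, int] = (1_000, 100_000)
    interval_choices: tuple[int, ...] = (1, 2, 3, 5)  # years
    service_range: tuple[int, int] = (50, 1_000)  # currency/patient
    duration_range: tuple[int, int] = (2, 60)  # minutes/patient
    sd_fraction: float = 0.2  # duration SD as a fraction of the mean
    direct_cost_range: tuple[int, int] = (10, 500)  # currency/patient
    p_direct_cost: float = 0.2
    p_per_patient_recurring: float = 0.25

    def __post_init__(self) -> None:
        for name in ("n_resources", "n_steps", "n_capital", "n_recurring", "n_services"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("salary_range", "working_time_range", "capital_range",
                     "recurring_range", "service_range", "duration_range",
                     "direct_cost_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be ordered and non-negative")
        if self.n_steps > 0 and self.n_resources == 0 and self.p_direct_cost < 1:
            raise ValueError("timed steps require at least one resource")


@dataclass(frozen=True)
class GroundTruth:
    """Sums accumulated during generation, independent of the engine.

    ``capital`` records (purchase, write-off years) pairs so the expected
    total can be formed for any horizon.
    """

    fixed_annual: Fraction
    per_patient: Fraction
    capital: tuple[tuple[Fraction, Fraction], ...]

    def expected_total(self, h: Horizon) -> Fraction:
        years = h.years
        total = sum((cost * min(years, w) / w for cost, w in self.capital), Fraction(0))
        total += years * self.fixed_annual
        total += years * h.annual_patients * self.per_patient
        return total


def _cents(rng: random.Random, lo: int, hi: int) -> Fraction:
    """A uniform whole-cent amount in [lo, hi] currency units."""
    return Fraction(rng.randint(lo * 100, hi * 100), 100)


def generate_scenario(cfg: GeneratorConfig) -> tuple[Scenario, GroundTruth]:
    """Draw one random scenario and its independently kept totals."""
    rng = random.Random(cfg.seed)
    fixed_annual = Fraction(0)
    per_patient = Fraction(0)
    capital: list[tuple[Fraction, Fraction]] = []

    resources = []
    for i in range(cfg.n_resources):
        salary = _cents(rng, *cfg.salary_range)
        minutes = Fraction(rng.randint(*cfg.working_time_range))
        resources.append(Resource(f"resource-{i}", annual_salary_cost=salary,
                                  annual_working_time=minutes))

    steps = []
    for i in range(cfg.n_steps):
        if cfg.n_resources > 0 and rng.random() >= cfg.p_direct_cost:
            res = rng.choice(resources)
            duration = Fraction(rng.randint(*cfg.duration_range))
            sd = as_rational(round(float(duration) * cfg.sd_fraction * rng.random(), 2))
            steps.append(WorkflowStep(f"step-{i}", resource=res.name,
                                      mean_duration=duration, duration_sd=sd))
            per_patient += duration * res.annual_salary_cost / res.annual_working_time
        else:
            cost = _cents(rng, *cfg.direct_cost_range)
            steps.append(WorkflowStep(f"step-{i}", direct_cost_override=cost))
            per_patient += cost

    capital_items = []
    for i in range(cfg.n_capital):
        cost = _cents(rng, *cfg.capital_range)
        writeoff = Fraction(rng.choice(cfg.writeoff_choices))
        capital_items.append(CapitalItem(f"capital-{i}", purchase_cost=cost,
                                         writeoff_years=writeoff))
        capital.append((cost, writeoff))

    recurring = []
    for i in range(cfg.n_recurring):
        amount = _cents(rng, *cfg.recurring_range)
        if rng.random() < cfg.p_per_patient_recurring:
            recurring.append(RecurringCost(f"recurring-{i}", amount=amount,
                                           interval_years=1, scaling="per_patient"))
            per_patient += amount
        else:
            interval = Fraction(rng.choice(cfg.interval_choices))
            recurring.append(RecurringCost(f"recurring-{i}", amount=amount,
                                           interval_years=interval))
            fixed_annual += amount / interval

    services = []
    for i in range(cfg.n_services):
        price = _cents(rng, *cfg.service_range)
        services.append(PurchasedService(f"service-{i}", unit_price=price))
        per_patient += price

    scenario = Scenario(
        name=f"synthetic-{cfg.seed}",
        resources=tuple(resources),
        steps=tuple(steps),
        capital_items=tuple(capital_items),
        recurring_costs=tuple(recurring),
        services=tuple(services),
    )
    truth = GroundTruth(fixed_annual=fixed_annual, per_patient=per_patient,
                        capital=tuple(capital))
    return scenario, truth


# ---------------------------------------------------------------------------
# Monte-Carlo timing sweep
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StochasticSummary:
    """Distribution of the horizon total under step-timing uncertainty."""

    mean: float
    sd: float
    p2_5: float
    p97_5: float
    n_draws: int
    deterministic_total: float
    degenerate: bool  # no timed step has positive SD


def stochastic_cost_sweep(s: Scenario, h: Horizon, n_draws: int,
                          seed: int) -> StochasticSummary:
    """Propagate step-timing variability into the horizon total.

    Each timed step's duration is drawn per replicate from a normal with
    the step's mean and SD, truncated at zero (durations cannot be
    negative); direct-cost steps and all non-personnel costs are
    deterministic.  Returns the mean, SD and central 95% interval of the
    total, flagged degenerate when every step is deterministic.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be > 0")
    rng = np.random.default_rng(seed)

    base_report = total_horizon_cost(s, h)
    deterministic = float(base_report.total_horizon_cost)

    # total without the timed-step contribution, as a float base
    timed = [st for st in s.steps if st.direct_cost_override is None]
    timed_cost = sum((step_cost_per_patient(st, s) for st in timed), Fraction(0))
    base = deterministic - float(h.years * h.annual_patients * timed_cost)

    patients = float(h.years * h.annual_patients)
    totals = np.full(n_draws, base)
    any_variance = False
    for st in timed:
        ccr = float(capacity_cost_rate(s.resource(st.resource)))
        mean, sd = float(st.mean_duration), float(st.duration_sd)
        if sd > 0:
            any_variance = True
            durations = np.clip(rng.normal(mean, sd, size=n_draws), 0.0, None)
        else:
            durations = np.full(n_draws, mean)
        totals += patients * ccr * durations

    lo, hi = np.percentile(totals, [2.5, 97.5])
    return StochasticSummary(
        mean=float(totals.mean()),
        sd=float(totals.std(ddof=1)) if n_draws > 1 else 0.0,
        p2_5=float(lo),
        p97_5=float(hi),
        n_draws=n_draws,
        deterministic_total=deterministic,
        degenerate=not any_variance,
    )
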