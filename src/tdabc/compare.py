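"""Two-scenario comparison: savings, cost-vs-volume sweep, break-even.

Because the horizon total of any scenario is affine in the annual
patient volume,

    total(n) = A + B * n,
    A = capital charge + years x fixed annual costs,
    B = years x per-patient variable cost,

the break-even volume between two scenarios is the closed-form crossover
``(A_b - A_a) / (B_a - B_b)``.  Savings are reported with the first
scenario as the candidate: positive savings mean scenario ``a`` is
cheaper than scenario ``b``.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .engine import (
    annual_fixed_cost,
    capital_charge,
    per_patient_variable_cost,
    total_horizon_cost,
)
from .model import Horizon, Scenario, as_rational, round_half_up

__all__ = [
    "Savings",
    "BreakEven",
    "ComparisonResult",
    "SensitivityEntry",
    "linear_form",
    "savings_at",
    "break_even_volume",
    "sweep",
    "one_at_a_time_sensitivity",
]


@dataclass(frozen=True)
class Savings:
    """Saving achieved by scenario A relative to scenario B.

    ``fraction`` is the saving as a share of B's total (None when B's
    total is zero).  Positive = A cheaper.
    """

    amount: Fraction
    fraction: Optional[Fraction]
    total_a: Fraction
    total_b: Fraction


@dataclass(frozen=True)
class BreakEven:
    """Crossover volume: the exact real solution and its half-up report."""

    exact: Fraction
    reported: int


@dataclass(frozen=True)
class ComparisonResult:
    """Cost-vs-volume sweep of two scenarios over a horizon of ``years``."""

    scenario_a: str
    scenario_b: str
    years: Fraction
    volume_grid: tuple[Fraction, ...]
    totals_a: tuple[Fraction, ...]
    totals_b: tuple[Fraction, ...]
    savings: tuple[Fraction, ...]  # B - A at each volume
    break_even: Optional[BreakEven]

    @property
    def break_even_exact(self) -> Optional[Fraction]:
        return self.break_even.exact if self.break_even else None

    @property
    def break_even_reported(self) -> Optional[int]:
        return self.break_even.reported if self.break_even else None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "annual_patients": [float(v) for v in self.volume_grid],
            "total_a": [float(t) for t in self.totals_a],
            "total_b": [float(t) for t in self.totals_b],
            "savings": [float(s) for s in self.savings],
        })

    def to_csv(self) -> str:
        return self.to_dataframe().to_csv(index=False)

    def plot(self, path: Union[str, Path]) -> None:
        """Two-line total-cost-vs-volume chart, marking the break-even."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        x = [float(v) for v in self.volume_grid]
        ax.plot(x, [float(t) for t in self.totals_a], label=self.scenario_a)
        ax.plot(x, [float(t) for t in self.totals_b], label=self.scenario_b)
        if self.break_even is not None:
            ax.axvline(float(self.break_even.exact), color="grey", ls="--", lw=0.8)
            ax.annotate(f"break-even {self.break_even.reported}",
                        (float(self.break_even.exact), ax.get_ylim()[0]),
                        textcoords="offset points", xytext=(4, 8), fontsize=8)
        ax.set_xlabel("patients per year")
        ax.set_ylabel(f"total cost over {self.years} years")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def linear_form(s: Scenario, years) -> tuple[Fraction, Fraction]:
    """Intercept and slope of ``total(n) = A + B*n`` for a scenario."""
    years = as_rational(years)
    fixed = sum((capital_charge(item, years) for item in s.capital_items), Fraction(0))
    fixed += years * annual_fixed_cost(s)
    slope = years * per_patient_variable_cost(s)
    return fixed, slope


def savings_at(a: Scenario, b: Scenario, h: Horizon) -> Savings:
    """Horizon-total saving of scenario ``a`` versus scenario ``b``."""
    total_a = total_horizon_cost(a, h).total_horizon_cost
    total_b = total_horizon_cost(b, h).total_horizon_cost
    amount = total_b - total_a
    fraction = amount / total_b if total_b != 0 else None
    return Savings(amount=amount, fraction=fraction, total_a=total_a, total_b=total_b)


def break_even_volume(a: Scenario, b: Scenario, years) -> Optional[BreakEven]:
    """Annual volume at which the two horizon totals are equal.

    Returns ``None`` when the cost lines are parallel (equal slopes) or
    when the crossover lies at negative volume.
    """
    fixed_a, slope_a = linear_form(a, years)
    fixed_b, slope_b = linear_form(b, years)
    if slope_a == slope_b:
        return None
    exact = (fixed_a - fixed_b) / (slope_b - slope_a)
    if exact < 0:
        return None
    return BreakEven(exact=exact, reported=round_half_up(exact))


def sweep(a: Scenario, b: Scenario, years,
          volumes: Sequence) -> ComparisonResult:
    """Evaluate both scenarios on a volume grid and locate the break-even."""
    if len(volumes) == 0:
        raise ValueError("volume grid must be non-empty")
    grid = tuple(as_rational(v) for v in volumes)
    if any(v < 0 for v in grid):
        raise ValueError("volumes must be non-negative")
    years = as_rational(years)
    totals_a, totals_b, savings = [], [], []
    for n in grid:
        h = Horizon(years=years, annual_patients=n)
        ta = total_horizon_cost(a, h).total_horizon_cost
        tb = total_horizon_cost(b, h).total_horizon_cost
        totals_a.append(ta)
        totals_b.append(tb)
        savings.append(tb - ta)
    return ComparisonResult(
        scenario_a=a.name,
        scenario_b=b.name,
        years=years,
        volume_grid=grid,
        totals_a=tuple(totals_a),
        totals_b=tuple(totals_b),
        savings=tuple(savings),
        break_even=break_even_volume(a, b, years),
    )


# ---------------------------------------------------------------------------
# One-at-a-time sensitivity (extension)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityEntry:
    """Effect on the saving of perturbing one scalar input by +/-p."""

    scenario: str
    parameter: str
    base_value: Fraction
    savings_up: Fraction  # saving when the input is scaled by (1+p)
    savings_down: Fraction
    magnitude: Fraction  # max absolute change vs the baseline saving


def _scalar_fields(s: Scenario):
    """Yield (category, index, field_name, value) for every scalar input."""
    specs = {
        "resources": ("annual_salary_cost", "annual_working_time", "ccr_override"),
        "steps": ("mean_duration", "duration_sd", "direct_cost_override"),
        "capital_items": ("purchase_cost", "writeoff_years", "allocation_fraction"),
        "recurring_costs": ("amount", "interval_years"),
        "services": ("unit_price",),
    }
    for category, names in specs.items():
        for i, item in enumerate(getattr(s, category)):
            for fname in names:
                value = getattr(item, fname)
                if value is None:
                    continue
                yield category, i, item.name, fname, value


def _perturbed(s: Scenario, category: str, index: int, fname: str,
               factor: Fraction) -> Scenario:
    items = list(getattr(s, category))
    items[index] = replace(items[index], **{fname: getattr(items[index], fname) * factor})
    return replace(s, **{category: tuple(items)})


def one_at_a_time_sensitivity(a: Scenario, b: Scenario, h: Horizon,
                              perturbation) -> list[SensitivityEntry]:
    """Rank scalar inputs of both scenarios by their leverage on the saving.

    Each input is scaled by ``1 +/- perturbation`` in turn and the saving
    of ``a`` versus ``b`` recomputed; entries are sorted by the largest
    absolute change.  Inputs the deterministic engine never reads
    (``duration_sd``) rank at zero.
    """
    p = as_rational(perturbation)
    if p < 0:
        raise ValueError("perturbation must be >= 0")
    base = savings_at(a, b, h).amount
    entries: list[SensitivityEntry] = []
    for which, scenario in (("a", a), ("b", b)):
        for category, i, item_name, fname, value in _scalar_fields(scenario):
            results = {}
            for sign, factor in (("up", 1 + p), ("down", 1 - p)):
                mod = _perturbed(scenario, category, i, fname, factor)
                pair = (mod, b) if which == "a" else (a, mod)
                results[sign] = savings_at(*pair, h).amount
            magnitude = max(abs(results["up"] - base), abs(results["down"] - base))
            entries.append(SensitivityEntry(
                scenario=scenario.name,
                parameter=f"{category}[{item_name!r}].{fname}",
                base_value=value,
                savings_up=results["up"],
                savings_down=results["down"],
                magnitude=magnitude,
            ))
    entries.sort(key=lambda e: (-e.magnitude, e.scenario, e.parameter))
    return entries
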