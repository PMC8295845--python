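"""Domain types and scenario-file schema for workflow costing.

A *scenario* describes one clinical workflow as the cost accountant sees
it: occupational groups with capacity cost rates, timed per-patient steps,
one-time capital investments with linear write-off, recurring costs
(annual or interval-based, fixed or patient-scaled) and externally
purchased per-patient services.

All monetary amounts, durations and rates are held as exact rationals
(:class:`fractions.Fraction`).  Rounding to whole currency units is a
display concern only and never feeds back into arithmetic; see
:func:`round_half_up`.

Scenario files are YAML or JSON mappings with the top-level keys
``name``, ``currency``, ``resources``, ``steps``, ``capital_items``,
``recurring_costs`` and ``services``.  Non-integer numbers may be written
either as decimals (``108.33``) or as exact ``"p/q"`` strings
(``"603/14000"``); files written by :func:`save_scenario` use the latter
so that a save/load round trip is exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from fractions import Fraction
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "Rational",
    "as_rational",
    "round_half_up",
    "format_money",
    "Resource",
    "WorkflowStep",
    "CapitalItem",
    "RecurringCost",
    "PurchasedService",
    "Scenario",
    "Horizon",
    "ComponentCost",
    "CostReport",
    "Violation",
    "ScenarioError",
    "ScenarioValidationError",
    "ResourceReferenceError",
    "validate_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
    "load_scenario",
    "save_scenario",
]

Rational = Fraction
NumberLike = Union[int, float, str, Fraction]

RECURRING_SCALINGS = ("fixed_annual", "per_patient")


def as_rational(value: NumberLike) -> Fraction:
    """Coerce a number-like value to an exact :class:`Fraction`.

    Floats are converted through their shortest decimal repr, so the YAML
    literal ``0.1`` becomes exactly 1/10 rather than the binary float.
    Strings accept decimals, scientific notation and ``"p/q"`` forms.
    """
    if isinstance(value, bool):
        raise TypeError("booleans are not valid numeric inputs")
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        if not math.isfinite(value):
            raise ValueError(f"non-finite number: {value!r}")
        return Fraction(repr(value))
    if isinstance(value, str):
        return Fraction(value.strip())
    raise TypeError(f"cannot interpret {value!r} as a number")


def _opt_rational(value: Optional[NumberLike]) -> Optional[Fraction]:
    return None if value is None else as_rational(value)


def round_half_up(x: Fraction) -> int:
    """Round to the nearest integer, halves toward +infinity.

    This is the display convention for whole-currency cells and for the
    reported break-even volume (280.81 -> 281, 130.37 -> 130,
    2,700,389.5 -> 2,700,390).
    """
    return math.floor(Fraction(x) + Fraction(1, 2))


def format_money(x: Fraction) -> str:
    """Whole-unit, half-up, thousands-separated display string."""
    return f"{round_half_up(x):,}"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Resource:
    """An occupational group supplying timed capacity.

    The capacity cost rate (CCR, currency per minute) is
    ``annual_salary_cost / annual_working_time`` unless ``ccr_override``
    pins it directly.  Working time is in minutes per year so that step
    durations in minutes multiply straight into currency.
    """

    name: str
    annual_salary_cost: Fraction = Fraction(0)
    annual_working_time: Fraction = Fraction(0)
    ccr_override: Optional[Fraction] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "annual_salary_cost", as_rational(self.annual_salary_cost))
        object.__setattr__(self, "annual_working_time", as_rational(self.annual_working_time))
        object.__setattr__(self, "ccr_override", _opt_rational(self.ccr_override))


@dataclass(frozen=True)
class WorkflowStep:
    """A per-patient activity: either timed work by a resource, or a
    direct per-patient cost.

    Exactly one of (``resource`` + ``mean_duration``) or
    ``direct_cost_override`` determines the step's cost.
    ``duration_sd`` is informational; only the stochastic sweep uses it.
    """

    name: str
    resource: Optional[str] = None
    mean_duration: Fraction = Fraction(0)
    duration_sd: Fraction = Fraction(0)
    direct_cost_override: Optional[Fraction] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_duration", as_rational(self.mean_duration))
        object.__setattr__(self, "duration_sd", as_rational(self.duration_sd))
        object.__setattr__(self, "direct_cost_override", _opt_rational(self.direct_cost_override))


@dataclass(frozen=True)
class CapitalItem:
    """A one-time investment written off linearly over ``writeoff_years``.

    ``allocation_fraction`` (default 1) is the share of the investment
    attributed to the costed patient group, for departments whose scanner
    also serves other groups.
    """

    name: str
    purchase_cost: Fraction = Fraction(0)
    writeoff_years: Fraction = Fraction(10)
    allocation_fraction: Fraction = Fraction(1)

    def __post_init__(self) -> None:
        object.__setattr__(self, "purchase_cost", as_rational(self.purchase_cost))
        object.__setattr__(self, "writeoff_years", as_rational(self.writeoff_years))
        object.__setattr__(self, "allocation_fraction", as_rational(self.allocation_fraction))


@dataclass(frozen=True)
class RecurringCost:
    """A maintenance or consumable cost.

    ``fixed_annual`` items annualize as ``amount / interval_years``
    (e.g. an X-ray tube replaced once in three years); ``per_patient``
    items scale with the annual volume.
    """

    name: str
    amount: Fraction = Fraction(0)
    interval_years: Fraction = Fraction(1)
    scaling: str = "fixed_annual"

    def __post_init__(self) -> None:
        object.__setattr__(self, "amount", as_rational(self.amount))
        object.__setattr__(self, "interval_years", as_rational(self.interval_years))


@dataclass(frozen=True)
class PurchasedService:
    """A per-patient service bought from an external provider."""

    name: str
    unit_price: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit_price", as_rational(self.unit_price))


@dataclass(frozen=True)
class Scenario:
    """A named workflow bundling resources, steps and costs."""

    name: str
    resources: tuple[Resource, ...] = ()
    steps: tuple[WorkflowStep, ...] = ()
    capital_items: tuple[CapitalItem, ...] = ()
    recurring_costs: tuple[RecurringCost, ...] = ()
    services: tuple[PurchasedService, ...] = ()
    currency: str = "EUR"

    def __post_init__(self) -> None:
        object.__setattr__(self, "resources", tuple(self.resources))
        object.__setattr__(self, "steps", tuple(self.steps))
        object.__setattr__(self, "capital_items", tuple(self.capital_items))
        object.__setattr__(self, "recurring_costs", tuple(self.recurring_costs))
        object.__setattr__(self, "services", tuple(self.services))

    def resource(self, name: str) -> Resource:
        for r in self.resources:
            if r.name == name:
                return r
        raise ResourceReferenceError(f"unknown resource {name!r} in scenario {self.name!r}")


@dataclass(frozen=True)
class Horizon:
    """Evaluation horizon: number of years and annual patient volume."""

    years: Fraction = Fraction(10)
    annual_patients: Fraction = Fraction(300)

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", as_rational(self.years))
        object.__setattr__(self, "annual_patients", as_rational(self.annual_patients))

    @property
    def total_patients(self) -> Fraction:
        return self.years * self.annual_patients


@dataclass(frozen=True)
class ComponentCost:
    """One costed component of a report.

    ``category`` is ``capital``, ``recurring``, ``personnel`` or
    ``service``; ``annual_cost`` is the capital charge spread per year for
    capital items.
    """

    name: str
    category: str
    annual_cost: Fraction
    horizon_cost: Fraction
    per_patient: Optional[Fraction]


@dataclass(frozen=True)
class CostReport:
    """Totals and breakdowns for one scenario at one horizon.

    All fields are exact; ``per_patient_*`` fields are ``None`` (and
    ``per_patient_defined`` False) when the horizon treats no patients.
    Shares are fractions of the horizon total: personnel covers timed
    steps, equipment covers capital plus recurring costs, services covers
    purchased services; the three sum to 1 for a nonzero total.
    """

    scenario_name: str
    currency: str
    years: Fraction
    annual_patients: Fraction
    capital_total: Fraction
    operational_total: Fraction
    total_horizon_cost: Fraction
    annual_operational_cost: Fraction
    components: tuple[ComponentCost, ...]
    per_patient_total: Optional[Fraction]
    per_patient_by_component: Optional[dict[str, Fraction]]
    personnel_share: Optional[Fraction]
    equipment_share: Optional[Fraction]
    services_share: Optional[Fraction]
    per_patient_defined: bool


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """A single invariant violation, naming the offending field."""

    category: str  # "schema" | "value" | "reference" | "duplicate"
    location: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.category}] {self.location}: {self.message}"


class ScenarioError(Exception):
    """Base class for scenario loading/validation failures."""


class ScenarioValidationError(ScenarioError):
    def __init__(self, violations: Sequence[Violation]):
        self.violations = list(violations)
        super().__init__("; ".join(str(v) for v in violations) or "invalid scenario")


class ResourceReferenceError(ScenarioError):
    """A workflow step references a resource the scenario does not define."""


def _dup_names(items: Iterable[Any], location: str) -> list[Violation]:
    seen: set[str] = set()
    out = []
    for it in items:
        if it.name in seen:
            out.append(Violation("duplicate", f"{location}[{it.name!r}]", "duplicate name"))
        seen.add(it.name)
    return out


def validate_scenario(s: Scenario) -> list[Violation]:
    """Check every type invariant; return violations instead of raising."""
    v: list[Violation] = []
    for cat in ("resources", "steps", "capital_items", "recurring_costs", "services"):
        v.extend(_dup_names(getattr(s, cat), cat))

    for r in s.resources:
        loc = f"resources[{r.name!r}]"
        if r.ccr_override is None and r.annual_working_time <= 0:
            v.append(Violation("value", f"{loc}.annual_working_time",
                               "must be > 0 when ccr_override is absent"))
        ccr = r.ccr_override if r.ccr_override is not None else (
            r.annual_salary_cost / r.annual_working_time if r.annual_working_time > 0 else None)
        if ccr is not None and ccr < 0:
            v.append(Violation("value", f"{loc}", "capacity cost rate must be >= 0"))

    names = {r.name for r in s.resources}
    for st in s.steps:
        loc = f"steps[{st.name!r}]"
        if st.mean_duration < 0:
            v.append(Violation("value", f"{loc}.mean_duration", "must be >= 0"))
        if st.duration_sd < 0:
            v.append(Violation("value", f"{loc}.duration_sd", "must be >= 0"))
        timed = st.resource is not None
        direct = st.direct_cost_override is not None
        if timed == direct:
            v.append(Violation("value", loc,
                               "exactly one of resource+mean_duration or "
                               "direct_cost_override must determine the cost"))
        if timed and st.resource not in names:
            v.append(Violation("reference", f"{loc}.resource",
                               f"unknown resource {st.resource!r}"))
        if direct and st.direct_cost_override < 0:
            v.append(Violation("value", f"{loc}.direct_cost_override", "must be >= 0"))

    for c in s.capital_items:
        loc = f"capital_items[{c.name!r}]"
        if c.purchase_cost < 0:
            v.append(Violation("value", f"{loc}.purchase_cost", "must be >= 0"))
        if c.writeoff_years <= 0:
            v.append(Violation("value", f"{loc}.writeoff_years", "must be > 0"))
        if not (0 <= c.allocation_fraction <= 1):
            v.append(Violation("value", f"{loc}.allocation_fraction", "must be in [0, 1]"))

    for rc in s.recurring_costs:
        loc = f"recurring_costs[{rc.name!r}]"
        if rc.amount < 0:
            v.append(Violation("value", f"{loc}.amount", "must be >= 0"))
        if rc.interval_years <= 0:
            v.append(Violation("value", f"{loc}.interval_years", "must be > 0"))
        if rc.scaling not in RECURRING_SCALINGS:
            v.append(Violation("value", f"{loc}.scaling",
                               f"must be one of {RECURRING_SCALINGS}"))

    for sv in s.services:
        if sv.unit_price < 0:
            v.append(Violation("value", f"services[{sv.name!r}].unit_price", "must be >= 0"))

    return v


# ---------------------------------------------------------------------------
# Schema (de)serialization
# ---------------------------------------------------------------------------

_LIST_KEYS = ("resources", "steps", "capital_items", "recurring_costs", "services")
_TYPES = {
    "resources": Resource,
    "steps": WorkflowStep,
    "capital_items": CapitalItem,
    "recurring_costs": RecurringCost,
    "services": PurchasedService,
}
_NUMERIC_FIELDS = {
    "annual_salary_cost", "annual_working_time", "ccr_override",
    "mean_duration", "duration_sd", "direct_cost_override",
    "purchase_cost", "writeoff_years", "allocation_fraction",
    "amount", "interval_years", "unit_price",
}


def _num_out(x: Optional[Fraction]) -> Optional[Union[int, str]]:
    if x is None:
        return None
    x = Fraction(x)
    return int(x) if x.denominator == 1 else str(x)


def scenario_to_dict(s: Scenario) -> dict:
    """Plain-data form of a scenario (exact; JSON/YAML-safe)."""
    out: dict[str, Any] = {"name": s.name, "currency": s.currency}
    for key in _LIST_KEYS:
        rows = []
        for item in getattr(s, key):
            row: dict[str, Any] = {}
            for f in fields(item):
                val = getattr(item, f.name)
                if f.name in _NUMERIC_FIELDS:
                    val = _num_out(val)
                if val is None:
                    continue
                row[f.name] = val
            rows.append(row)
        out[key] = rows
    return out


def _coerce_item(cls, row: Mapping[str, Any], location: str,
                 violations: list[Violation]):
    if not isinstance(row, Mapping):
        violations.append(Violation("schema", location, "expected a mapping"))
        return None
    known = {f.name for f in fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, val in row.items():
        if key not in known:
            violations.append(Violation("schema", f"{location}.{key}", "unknown field"))
            continue
        if key in _NUMERIC_FIELDS and val is not None:
            try:
                val = as_rational(val)
            except (ValueError, TypeError, ZeroDivisionError):
                violations.append(Violation("schema", f"{location}.{key}",
                                            f"not a number: {val!r}"))
                continue
        kwargs[key] = val
    if "name" not in kwargs or not isinstance(kwargs.get("name"), str):
        violations.append(Violation("schema", f"{location}.name",
                                    "required text field"))
        return None
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:  # non-numeric text fields etc.
        violations.append(Violation("schema", location, str(exc)))
        return None


def scenario_from_dict(data: Mapping[str, Any]) -> tuple[Optional[Scenario], list[Violation]]:
    """Build a scenario from plain data, collecting (never raising) violations.

    Returns ``(scenario, violations)``; the scenario is ``None`` only when
    the document is too malformed to build one at all.  Validation is
    total: any parseable document yields either a scenario or a finite
    violation list.
    """
    violations: list[Violation] = []
    if not isinstance(data, Mapping):
        return None, [Violation("schema", "<document>", "expected a mapping at top level")]
    name = data.get("name")
    if not isinstance(name, str) or not name:
        violations.append(Violation("schema", "name", "required text field"))
        name = "<unnamed>"
    currency = data.get("currency", "EUR")
    if not isinstance(currency, str):
        violations.append(Violation("schema", "currency", "must be text"))
        currency = "EUR"
    for key in data:
        if key not in ("name", "currency", *_LIST_KEYS):
            violations.append(Violation("schema", key, "unknown top-level key"))

    parts: dict[str, list] = {}
    for key in _LIST_KEYS:
        raw = data.get(key, [])
        if raw is None:
            raw = []
        if not isinstance(raw, Sequence) or isinstance(raw, (str, bytes)):
            violations.append(Violation("schema", key, "expected a list"))
            raw = []
        items = []
        for i, row in enumerate(raw):
            item = _coerce_item(_TYPES[key], row, f"{key}[{i}]", violations)
            if item is not None:
                items.append(item)
        parts[key] = items

    scenario = Scenario(name=name, currency=currency, **parts)
    violations.extend(validate_scenario(scenario))
    return scenario, violations


def load_scenario(path: Union[str, Path]) -> Scenario:
    """Load and validate a scenario file (YAML or JSON).

    Raises :class:`ResourceReferenceError` on dangling step-resource
    references and :class:`ScenarioValidationError` on any other schema
    or invariant violation.
    """
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ScenarioValidationError(
            [Violation("schema", str(path), f"unparseable file: {exc}")]) from exc

    scenario, violations = scenario_from_dict(data)
    if violations:
        refs = [v for v in violations if v.category == "reference"]
        if refs and len(refs) == len(violations):
            raise ResourceReferenceError("; ".join(str(v) for v in refs))
        raise ScenarioValidationError(violations)
    assert scenario is not None
    return scenario


def save_scenario(s: Scenario, path: Union[str, Path]) -> None:
    """Write a scenario to YAML (or JSON for a ``.json`` path), exactly."""
    path = Path(path)
    data = scenario_to_dict(s)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
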