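"""Time-driven activity-based costing engine.

Cost model
----------
Each resource has a capacity cost rate (CCR) in currency per minute,
``annual salary cost / annual working time``.  A timed step costs
``mean duration x CCR`` per patient; a direct-cost step costs its
override.  Capital items are written off linearly: the charge attributed
to a horizon of ``Y`` years is ``purchase x allocation x min(Y, W)/W``
for write-off period ``W``.  Recurring costs annualize as
``amount / interval_years`` when fixed, or ``amount x n`` when scaled
per patient.  Overheads (electricity, cleaning, ...) are deliberately
outside the model.

The total cost over a horizon of ``Y`` years at ``n`` patients/year is

    total(Y, n) = capital charge + Y * (fixed annual costs)
                + Y * n * (per-patient step + service costs)

i.e. affine in ``n`` with intercept capital + fixed and slope
``Y x`` per-patient variable cost; the comparison module exploits this
closed form for break-even analysis.

All arithmetic is exact (Fractions); whole-currency rounding happens only
in the render/serialize helpers.
"""

from __future__ import annotations

import io
from fractions import Fraction
from typing import Optional, Union

import pandas as pd

from .model import (
    CapitalItem,
    ComponentCost,
    CostReport,
    Horizon,
    PurchasedService,
    RecurringCost,
    Resource,
    ResourceReferenceError,
    Scenario,
    WorkflowStep,
    format_money,
    round_half_up,
)

__all__ = [
    "capacity_cost_rate",
    "step_cost_per_patient",
    "annualized_capital",
    "capital_charge",
    "annualized_recurring",
    "per_patient_variable_cost",
    "annual_fixed_cost",
    "annual_operational_cost",
    "total_horizon_cost",
    "cost_breakdown",
    "report_to_dataframe",
    "report_to_csv",
    "report_to_json_dict",
    "render_table",
]


def capacity_cost_rate(r: Resource) -> Fraction:
    """Currency per minute of a resource's capacity.

    Uses ``ccr_override`` when set, else salary / working time.
    """
    if r.ccr_override is not None:
        return r.ccr_override
    if r.annual_working_time == 0:
        raise ZeroDivisionError(
            f"resource {r.name!r}: annual_working_time is 0 and no ccr_override set")
    return r.annual_salary_cost / r.annual_working_time


def step_cost_per_patient(step: WorkflowStep, scenario: Scenario) -> Fraction:
    """Per-patient cost of one workflow step within its scenario."""
    if step.direct_cost_override is not None:
        return step.direct_cost_override
    if step.resource is None:
        raise ResourceReferenceError(
            f"step {step.name!r} has neither a resource nor a direct cost")
    resource = scenario.resource(step.resource)
    return step.mean_duration * capacity_cost_rate(resource)


def annualized_capital(item: CapitalItem) -> Fraction:
    """Linear write-off charge per year of the write-off period."""
    return item.purchase_cost * item.allocation_fraction / item.writeoff_years


def capital_charge(item: CapitalItem, horizon_years: Fraction) -> Fraction:
    """Capital charged to a horizon: full purchase when the write-off
    period fits inside the horizon, else the pro-rata share."""
    covered = min(Fraction(horizon_years), item.writeoff_years)
    return item.purchase_cost * item.allocation_fraction * covered / item.writeoff_years


def annualized_recurring(c: RecurringCost, annual_patients: Fraction) -> Fraction:
    """Cost per year of a recurring item at the given volume."""
    if c.scaling == "per_patient":
        return c.amount * Fraction(annual_patients)
    return c.amount / c.interval_years


def per_patient_variable_cost(s: Scenario) -> Fraction:
    """Sum of per-patient step and purchased-service costs."""
    total = Fraction(0)
    for step in s.steps:
        total += step_cost_per_patient(step, s)
    for service in s.services:
        total += service.unit_price
    for rc in s.recurring_costs:
        if rc.scaling == "per_patient":
            total += rc.amount
    return total


def annual_fixed_cost(s: Scenario) -> Fraction:
    """Sum of fixed-annual recurring costs (volume-independent)."""
    return sum((annualized_recurring(rc, Fraction(0))
                for rc in s.recurring_costs if rc.scaling == "fixed_annual"),
               Fraction(0))


def annual_operational_cost(s: Scenario, annual_patients) -> Fraction:
    """Operational cost per year: recurring costs plus volume times the
    per-patient step and service costs."""
    n = Fraction(annual_patients)
    total = Fraction(0)
    for rc in s.recurring_costs:
        total += annualized_recurring(rc, n)
    for step in s.steps:
        total += n * step_cost_per_patient(step, s)
    for service in s.services:
        total += n * service.unit_price
    return total


def total_horizon_cost(s: Scenario, h: Horizon) -> CostReport:
    """Full-precision cost report for a scenario over a horizon.

    With zero annual patients the horizon total is still defined (capital
    plus fixed annual costs) but all per-patient figures are flagged
    undefined.
    """
    years, n = h.years, h.annual_patients
    patients = years * n

    components: list[ComponentCost] = []

    def add(name: str, category: str, annual: Fraction, horizon: Fraction) -> None:
        per_patient = horizon / patients if patients > 0 else None
        components.append(ComponentCost(name, category, annual, horizon, per_patient))

    capital_total = Fraction(0)
    for item in s.capital_items:
        charge = capital_charge(item, years)
        capital_total += charge
        add(item.name, "capital", charge / years if years else Fraction(0), charge)

    operational_total = Fraction(0)
    for rc in s.recurring_costs:
        annual = annualized_recurring(rc, n)
        operational_total += years * annual
        add(rc.name, "recurring", annual, years * annual)
    for step in s.steps:
        annual = n * step_cost_per_patient(step, s)
        operational_total += years * annual
        add(step.name, "personnel", annual, years * annual)
    for service in s.services:
        annual = n * service.unit_price
        operational_total += years * annual
        add(service.name, "service", annual, years * annual)

    total = capital_total + operational_total
    annual_operational = annual_operational_cost(s, n)

    if patients > 0:
        per_patient_total = total / patients
        by_component = {c.name: c.per_patient for c in components}
    else:
        per_patient_total = None
        by_component = None

    if total > 0:
        personnel = sum((c.horizon_cost for c in components if c.category == "personnel"),
                        Fraction(0))
        services = sum((c.horizon_cost for c in components if c.category == "service"),
                       Fraction(0))
        personnel_share = personnel / total
        services_share = services / total
        equipment_share = 1 - personnel_share - services_share
    else:
        personnel_share = equipment_share = services_share = None

    return CostReport(
        scenario_name=s.name,
        currency=s.currency,
        years=years,
        annual_patients=n,
        capital_total=capital_total,
        operational_total=operational_total,
        total_horizon_cost=total,
        annual_operational_cost=annual_operational,
        components=tuple(components),
        per_patient_total=per_patient_total,
        per_patient_by_component=by_component,
        personnel_share=personnel_share,
        equipment_share=equipment_share,
        services_share=services_share,
        per_patient_defined=patients > 0,
    )


_PARTITIONS = {
    "capital_vs_operational": {
        "capital": ("capital",),
        "operational": ("recurring", "personnel", "service"),
    },
    "personnel_vs_equipment": {
        "personnel": ("personnel",),
        "space_equipment": ("capital", "recurring"),
        "external_services": ("service",),
    },
}


def cost_breakdown(report: CostReport, partition: str) -> dict[str, dict[str, Optional[Fraction]]]:
    """Labelled shares of the horizon total under a partition.

    ``capital_vs_operational`` splits capital from everything recurring;
    ``personnel_vs_equipment`` splits timed personnel work from space and
    equipment, with externally purchased services as a third label (the
    conventional grouping when a workflow buys its imaging).  Shares are
    exact and sum to 1; for a zero total they are flagged ``None``.
    """
    if partition not in _PARTITIONS:
        raise ValueError(f"unknown partition {partition!r}; "
                         f"choose from {sorted(_PARTITIONS)}")
    out: dict[str, dict[str, Optional[Fraction]]] = {}
    total = report.total_horizon_cost
    for label, categories in _PARTITIONS[partition].items():
        horizon = sum((c.horizon_cost for c in report.components
                       if c.category in categories), Fraction(0))
        per_patient = (horizon / (report.years * report.annual_patients)
                       if report.per_patient_defined else None)
        share = horizon / total if total > 0 else None
        out[label] = {"horizon_cost": horizon, "per_patient": per_patient, "share": share}
    return out


# ---------------------------------------------------------------------------
# Serialization / rendering
# ---------------------------------------------------------------------------


def report_to_dataframe(report: CostReport) -> pd.DataFrame:
    """One row per component with unrounded float values."""
    rows = [
        {
            "name": c.name,
            "category": c.category,
            "annual_cost": float(c.annual_cost),
            "horizon_cost": float(c.horizon_cost),
            "per_patient_cost": float(c.per_patient) if c.per_patient is not None else None,
            "share": float(c.horizon_cost / report.total_horizon_cost)
            if report.total_horizon_cost > 0 else None,
        }
        for c in report.components
    ]
    return pd.DataFrame(rows, columns=["name", "category", "annual_cost",
                                       "horizon_cost", "per_patient_cost", "share"])


def report_to_csv(report: CostReport) -> str:
    return report_to_dataframe(report).to_csv(index=False)


def report_to_json_dict(report: CostReport) -> dict:
    """Nested mirror of the report with unrounded decimal values."""
    return {
        "scenario": report.scenario_name,
        "currency": report.currency,
        "years": float(report.years),
        "annual_patients": float(report.annual_patients),
        "total_horizon_cost": float(report.total_horizon_cost),
        "capital_total": float(report.capital_total),
        "operational_total": float(report.operational_total),
        "annual_operational_cost": float(report.annual_operational_cost),
        "per_patient_total": (float(report.per_patient_total)
                              if report.per_patient_defined else None),
        "per_patient_defined": report.per_patient_defined,
        "shares": {
            "personnel": float(report.personnel_share)
            if report.personnel_share is not None else None,
            "space_equipment": float(report.equipment_share)
            if report.equipment_share is not None else None,
            "external_services": float(report.services_share)
            if report.services_share is not None else None,
        },
        "components": [
            {
                "name": c.name,
                "category": c.category,
                "annual_cost": float(c.annual_cost),
                "horizon_cost": float(c.horizon_cost),
                "per_patient_cost": float(c.per_patient) if c.per_patient is not None else None,
            }
            for c in report.components
        ],
    }


def render_table(report: CostReport) -> str:
    """Human-readable cost table with whole-unit half-up rounding applied
    independently per cell (so summed rows can differ from summed cells
    by a unit, exactly as in published cost tables)."""
    buf = io.StringIO()
    cur = report.currency
    w = 58
    print(f"Scenario: {report.scenario_name}", file=buf)
    print(f"Horizon:  {report.years} years x {report.annual_patients} patients/year",
          file=buf)
    print("-" * (w + 26), file=buf)
    print(f"{'Cost component':<{w}}{'Horizon cost':>14}{'Per patient':>12}", file=buf)
    print("-" * (w + 26), file=buf)
    for c in report.components:
        per = format_money(c.per_patient) if c.per_patient is not None else "-"
        print(f"{c.name + ' (' + c.category + ')':<{w}}"
              f"{format_money(c.horizon_cost):>14}{per:>12}", file=buf)
    print("-" * (w + 26), file=buf)
    per_total = (format_money(report.per_patient_total)
                 if report.per_patient_defined else "undefined (0 patients)")
    for label, value in (("Total capital cost", report.capital_total),
                         ("Total operational cost", report.operational_total),
                         ("Annual operational cost", report.annual_operational_cost)):
        print(f"{label:<{w}}{format_money(value):>14}", file=buf)
    print(f"{'Total horizon cost (' + cur + ')':<{w}}"
          f"{format_money(report.total_horizon_cost):>14}{per_total:>12}", file=buf)
    return buf.getvalue()
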