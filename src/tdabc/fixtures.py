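"""Packaged study scenarios: MRI-only versus CT + MRI prostate
radiotherapy-planning workflows at a Finnish university hospital.

The MRI-only workflow plans treatment on MRI alone (dose calculation on a
synthetic CT derived from the MRI), so the department owns the MRI
scanner and staffs the acquisition.  The conventional CT + MRI workflow
owns a CT scanner, buys the MRI examination externally, and adds a
CT-to-MRI image-registration step.  Only the workflow steps whose costs
differ between the two routes are costed.

Published inputs are per-step *annual* euro figures at a reference
volume of 300 patients/year.  Each personnel step therefore carries a
``ccr_override`` stored as the exact rational
``annual figure / (300 x minutes)``, so engine output reproduces the
published table exactly; the salary-division CCR path is exercised by
synthetic scenarios instead.  Timing standard deviations are carried for
the stochastic sweep only.

The same three scenarios ship as YAML files (``mri_only.yaml``,
``ct_mri_internal.yaml``, ``ct_mri_external.yaml``) for use from the
command line; see :func:`fixture_path`.
"""

from __future__ import annotations

from fractions import Fraction
from importlib import resources
from pathlib import Path

from .model import (
    CapitalItem,
    Horizon,
    PurchasedService,
    RecurringCost,
    Resource,
    Scenario,
    ScenarioValidationError,
    Violation,
    WorkflowStep,
    as_rational,
)

__all__ = [
    "REFERENCE_ANNUAL_PATIENTS",
    "INTERNAL_MRI_PRICE",
    "EXTERNAL_MRI_PRICE",
    "mri_only_scenario",
    "ct_mri_scenario",
    "study_horizon",
    "fixture_path",
]

#: Annual prostate-cancer volume at which the published per-step annual
#: euro figures were stated; used only to back out per-minute rates.
REFERENCE_ANNUAL_PATIENTS = 300

#: Price of an MRI examination bought from the hospital's own radiology
#: department, and the upper price when bought from the private sector.
INTERNAL_MRI_PRICE = Fraction(320)
EXTERNAL_MRI_PRICE = Fraction(672)


def _pinned_rate(annual_cost: int, minutes: int) -> Fraction:
    """Per-minute rate implied by a published annual step cost."""
    return Fraction(annual_cost, REFERENCE_ANNUAL_PATIENTS * minutes)


def mri_only_scenario() -> Scenario:
    """MRI-only planning workflow: in-house MRI scanner, two timed steps."""
    return Scenario(
        name="MRI-only",
        currency="EUR",
        resources=(
            Resource("radiation therapist", ccr_override=_pinned_rate(7_236, 56)),
            Resource("radiation oncologist", ccr_override=_pinned_rate(6_030, 26)),
        ),
        steps=(
            WorkflowStep("MRI acquisition for treatment planning",
                         resource="radiation therapist",
                         mean_duration=56, duration_sd=5),
            WorkflowStep("structure contouring",
                         resource="radiation oncologist",
                         mean_duration=26, duration_sd=7),
        ),
        capital_items=(
            CapitalItem("MRI scanner (basic assembly)",
                        purchase_cost=1_409_513, writeoff_years=10),
            CapitalItem("scanner room renovation",
                        purchase_cost=200_000, writeoff_years=10),
        ),
        recurring_costs=(
            RecurringCost("scanner maintenance contract",
                          amount=71_603, interval_years=1),
            RecurringCost("MRI coil replacement (1/y)",
                          amount=25_000, interval_years=1),
        ),
        services=(),
    )


def ct_mri_scenario(external_price=INTERNAL_MRI_PRICE) -> Scenario:
    """CT + MRI planning workflow with the MRI examination purchased
    externally at ``external_price`` per patient (320 from the hospital's
    radiology department, up to 672 from the private sector)."""
    price = as_rational(external_price)
    if price < 0:
        raise ScenarioValidationError(
            [Violation("value", "services['external MRI examination'].unit_price",
                       "must be >= 0")])
    return Scenario(
        name=f"CT+MRI (external MRI {price} EUR)",
        currency="EUR",
        resources=(
            Resource("radiation therapist", ccr_override=_pinned_rate(1_734, 13)),
            Resource("physicist", ccr_override=_pinned_rate(735, 4)),
            Resource("radiation oncologist", ccr_override=_pinned_rate(6_306, 27)),
        ),
        steps=(
            WorkflowStep("CT acquisition for treatment planning",
                         resource="radiation therapist",
                         mean_duration=13, duration_sd=4),
            WorkflowStep("CT-MRI image registration",
                         resource="physicist",
                         mean_duration=4, duration_sd=1),
            WorkflowStep("structure contouring",
                         resource="radiation oncologist",
                         mean_duration=27, duration_sd=11),
        ),
        capital_items=(
            CapitalItem("CT scanner (basic assembly)",
                        purchase_cost=519_857, writeoff_years=10),
            CapitalItem("scanner room renovation",
                        purchase_cost=70_000, writeoff_years=10),
        ),
        recurring_costs=(
            RecurringCost("scanner maintenance contract",
                          amount=80_414, interval_years=1),
            # unit price back-computed from the annualized 32,500/y charge
            RecurringCost("X-ray tube replacement (1/3 y)",
                          amount=97_500, interval_years=3),
        ),
        services=(
            PurchasedService("external MRI examination", unit_price=price),
        ),
    )


def study_horizon() -> Horizon:
    """The study's evaluation window: 10 years at 300 patients/year."""
    return Horizon(years=10, annual_patients=300)


_FILES = {
    "mri_only": "mri_only.yaml",
    "ct_mri_internal": "ct_mri_internal.yaml",
    "ct_mri_external": "ct_mri_external.yaml",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged scenario file.

    ``name`` is one of ``mri_only``, ``ct_mri_internal`` (320/exam) or
    ``ct_mri_external`` (672/exam).
    """
    if name not in _FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FILES)}")
    return Path(resources.files("tdabc").joinpath("data", _FILES[name]))
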