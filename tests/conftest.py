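"""Shared fixtures and the event-by-event accounting oracle.

The ledger oracle accrues costs the slow way — per year, per patient,
per component — with exact rationals, entirely outside the engine's
closed-form path, and is the independent check on horizon totals.
"""

from fractions import Fraction

import pytest

from tdabc import (
    GeneratorConfig,
    Horizon,
    Scenario,
    ct_mri_scenario,
    generate_scenario,
    mri_only_scenario,
    study_horizon,
)
from tdabc.engine import capacity_cost_rate


@pytest.fixture(scope="session")
def mri_only() -> Scenario:
    return mri_only_scenario()


@pytest.fixture(scope="session")
def ct_mri_320() -> Scenario:
    return ct_mri_scenario(320)


@pytest.fixture(scope="session")
def ct_mri_672() -> Scenario:
    return ct_mri_scenario(672)


@pytest.fixture(scope="session")
def horizon() -> Horizon:
    return study_horizon()


def ledger_oracle(s: Scenario, h: Horizon) -> Fraction:
    """Brute-force total: amortize capital linearly, then walk every year
    and every patient adding each charge as it falls due."""
    years = int(h.years)
    n = int(h.annual_patients)
    assert h.years == years and h.annual_patients == n, "oracle needs integer horizons"

    total = Fraction(0)
    for item in s.capital_items:
        annual_writeoff = item.purchase_cost * item.allocation_fraction / item.writeoff_years
        for year in range(years):
            if year < item.writeoff_years:
                total += annual_writeoff

    per_patient = []
    for step in s.steps:
        if step.direct_cost_override is not None:
            per_patient.append(step.direct_cost_override)
        else:
            ccr = capacity_cost_rate(s.resource(step.resource))
            per_patient.append(step.mean_duration * ccr)
    for service in s.services:
        per_patient.append(service.unit_price)

    for _year in range(years):
        for rc in s.recurring_costs:
            if rc.scaling == "fixed_annual":
                total += rc.amount / rc.interval_years
        for _patient in range(n):
            for charge in per_patient:
                total += charge
            for rc in s.recurring_costs:
                if rc.scaling == "per_patient":
                    total += rc.amount

    return total


def random_scenario(seed: int, **overrides):
    """A small random scenario plus its generator-side ground truth."""
    cfg = GeneratorConfig(seed=seed, **overrides)
    return generate_scenario(cfg)
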