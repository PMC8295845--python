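# Methods

## Costing model

The engine implements time-driven activity-based costing (TDABC) for a
two-way comparison of radiotherapy-planning workflows. A scenario is a
bundle of:

- **resources** — occupational groups with a capacity cost rate (CCR),
  either derived as `annual_salary_cost / annual_working_time`
  (EUR/min; working time is stored in minutes/year so step durations in
  minutes multiply straight into currency) or pinned by `ccr_override`;
- **steps** — per-patient activities costing `mean_duration × CCR`, or
  a `direct_cost_override` per patient;
- **capital items** — one-time investments written off linearly over
  `writeoff_years`; a horizon of `Y` years is charged
  `purchase × allocation_fraction × min(Y, W)/W`;
- **recurring costs** — `amount / interval_years` per year when
  `fixed_annual` (an X-ray tube replaced every three years annualizes
  to a third of its price), or `amount × n` when `per_patient`;
- **purchased services** — flat per-patient prices.

The horizon total is `capital + Y·(fixed annual) + Y·n·(per-patient
variable)`, affine in the annual volume `n`. Assumptions: undiscounted
sums (no net-present-value correction), no overheads (electricity,
cleaning and similar are excluded by construction), linear write-off,
and consumables that do not scale with patient volume unless explicitly
declared `per_patient`. That last classification matters: treating coil
and tube replacements as fixed-annual is what makes the cost lines of
the two study workflows cross where they do.

## Exact arithmetic and display rounding

All quantities are `fractions.Fraction`. This is not decorative: the
CT + MRI total at 281 patients/year is exactly 2,700,389.5 EUR, a true
half-way case that binary floating point could tip either way. Rounding
is round-half-up (halves toward +∞) to whole currency units, applied
independently per displayed cell and never fed back into computation.
Summed-before-rounding therefore reproduces the familiar table artifact
where per-patient cells 173 + 23 + 268 + 108 print as a 573 partition
total. The reported break-even volume is the half-up rounding of the
exact rational crossover (280.807… → 281, 130.366… → 130); the exact
value is always carried alongside.

Scenario files serialize non-integer rationals as `"p/q"` strings so a
save/load round trip is field-for-field exact.

## Study scenarios

The packaged fixtures encode the two workflows of the underlying cost
study (10-year horizon, 300 patients/year reference volume, prices VAT
0%):

| | MRI-only | CT + MRI |
|---|---|---|
| scanner purchase | 1,409,513 | 519,857 |
| room renovation | 200,000 | 70,000 |
| maintenance /y | 71,603 | 80,414 |
| consumables | coil 25,000 /y | tube 97,500 per 3 y |
| timed steps (min) | MRI acq. 56, contouring 26 | CT acq. 13, registration 4, contouring 27 |
| external MRI /patient | — | 320 (internal) or 672 (private) |

The published inputs are per-step **annual euro figures** at the
reference volume, not salary tables, and the per-minute rates they
imply differ slightly between workflows (7,236/(300·56) ≈ 0.431 vs
1,734/(300·13) ≈ 0.445 EUR/min for the same occupational group).
The fixtures therefore pin each resource with a `ccr_override` stored
as the exact rational `annual figure / (300 × minutes)`, taking the
published euro figures as authoritative; the salary-division CCR path
is exercised by synthetic scenarios instead. The tube's 97,500 unit
price is back-computed from its published 32,500 EUR/y annualization at
one replacement per three years. Timing standard deviations (5, 7, 4,
1, 11 min) are carried on the steps but read only by the stochastic
sweep.

The `allocation_fraction` on capital items (default 1) supports
departments whose scanner also serves other patient groups; the study
fixtures attribute full capital to the costed group, which
*understates* the MRI-only saving.

## Synthetic scenarios and what they test

`generate_scenario(GeneratorConfig(seed))` draws random scenarios with
magnitudes typical of the domain — salaries 40–120 k/y, working time
80–120 k min/y, capital 50 k–2 M with 5–20-year write-offs, recurring
costs 1–100 k at 1–5-year intervals, services 50–1,000 per patient,
step times 2–60 min — and accumulates fixed-annual and per-patient sums
*during generation*, before any engine code runs. Monetary draws are
whole cents, keeping generated scenarios exact. A single integer seed
governs all randomness; equal seeds give byte-identical files.

Passing the generator-based properties shows the engine's accounting is
internally consistent (ledger equivalence, linearity in volume,
conservation of component sums, scale invariance), not that any real
department's inputs are well estimated: the generator draws components
independently and models no correlation between prices or between step
durations, and real cost structures (negotiated bundles, volume
discounts, shared infrastructure) are outside its scope.

The Monte-Carlo sweep (`stochastic_cost_sweep`) propagates step-timing
uncertainty only: each timed step's duration is drawn from a normal
with the step's mean and SD, truncated at zero. Normality is a
modelling choice — the timing studies behind the fixtures report only
mean ± SD — and with the fixture SDs the truncation is inactive in
practice (means sit 2.5–11 SDs above zero). Price uncertainty is not
modelled; the one-at-a-time sensitivity ranking
(`one_at_a_time_sensitivity`) is the deterministic counterpart for
that, scaling each scalar input by 1 ± p and ranking by the change in
the saving.

## Numerical and design choices

- **Break-even**: closed-form crossover of the two affine cost lines;
  `None` when slopes are equal or the crossover is negative, rather
  than a clamped 0. A bisection over black-box totals is kept in the
  test suite as an independent route to the same root.
- **Savings sign**: `savings_at(a, b, …) > 0` means the first scenario
  is cheaper; the fraction is reported relative to scenario B's total.
- **Degenerate inputs**: empty scenarios cost zero; a horizon with zero
  patients still accrues capital and fixed costs but flags all
  per-patient fields undefined; zero-variance scenarios make the
  stochastic sweep collapse to the deterministic total and are flagged
  `degenerate`.
- **Validation** is total and non-raising at the library level
  (`validate_scenario` returns a violation list naming each offending
  field); the file loader raises, distinguishing dangling resource
  references from other violations.
- **Problem sizes**: the property suites run on 1,000 seeded random
  scenarios for ledger equivalence (horizons of 1–6 years, up to 30
  patients/year for the event-by-event oracle, which walks every year
  and patient) and 10,000 draws for Monte-Carlo checks; the published
  figures themselves are desk-scale exact arithmetic.

## Known limitations

- Two-scenario comparisons only; no multi-way frontier.
- No discounting, inflation or price-year adjustment.
- Costs outside the differing workflow steps (treatment delivery,
  image guidance, follow-up) are not modelled, so totals are
  comparison totals, not full course-of-treatment costs.
- The stochastic sweep treats patients as exchangeable and step
  durations as independent across steps.
- Capital sharing across patient groups is expressed only through the
  static `allocation_fraction`; there is no utilization-based
  allocation model.
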