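name: CT+MRI (external MRI 672 EUR)
currency: EUR
resources:
- name: radiation therapist
  annual_salary_cost: 0
  annual_working_time: 0
  ccr_override: 289/650
- name: physicist
  annual_salary_cost: 0
  annual_working_time: 0
  ccr_override: 49/80
- name: radiation oncologist
  annual_salary_cost: 0
  annual_working_time: 0
  ccr_override: 1051/1350
steps:
- name: CT acquisition for treatment planning
  resource: radiation therapist
  mean_duration: 13
  duration_sd: 4
- name: CT-MRI image registration
  resource: physicist
  mean_duration: 4
  duration_sd: 1
- name: structure contouring
  resource: radiation oncologist
  mean_duration: 27
  duration_sd: 11
capital_items:
- name: CT scanner (basic assembly)
  purchase_cost: 519857
  writeoff_years: 10
  allocation_fraction: 1
- name: scanner room renovation
  purchase_cost: 70000
  writeoff_years: 10
  allocation_fraction: 1
recurring_costs:
- name: scanner maintenance contract
  amount: 80414
  interval_years: 1
  scaling: fixed_annual
- name: X-ray tube replacement (1/3 y)
  amount: 97500
  interval_years: 3
  scaling: fixed_annual
services:
- name: external MRI examination
  unit_price: 672
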