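name: MRI-only
currency: EUR
resources:
- name: radiation therapist
  annual_salary_cost: 0
  annual_working_time: 0
  ccr_override: 603/1400
- name: radiation oncologist
  annual_salary_cost: 0
  annual_working_time: 0
  ccr_override: 201/260
steps:
- name: MRI acquisition for treatment planning
  resource: radiation therapist
  mean_duration: 56
  duration_sd: 5
- name: structure contouring
  resource: radiation oncologist
  mean_duration: 26
  duration_sd: 7
capital_items:
- name: MRI scanner (basic assembly)
  purchase_cost: 1409513
  writeoff_years: 10
  allocation_fraction: 1
- name: scanner room renovation
  purchase_cost: 200000
  writeoff_years: 10
  allocation_fraction: 1
recurring_costs:
- name: scanner maintenance contract
  amount: 71603
  interval_years: 1
  scaling: fixed_annual
- name: MRI coil replacement (1/y)
  amount: 25000
  interval_years: 1
  scaling: fixed_annual
services: []
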