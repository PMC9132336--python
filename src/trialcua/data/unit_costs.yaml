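# Default unit-cost table, A$ 2018-19 financial year.
# Placeholder schedule values in the spirit of Australian MBS/PBS/AIHW
# reference prices; replace with a study-specific table for real analyses.
currency_year: "2018-19"
unit_costs:
  gp: 38.75
  psychologist: 150.00
  psychiatrist: 210.00
  diagnostic_test: 55.00
  medication_script: 31.50
  hospital_day: 2100.00
  ed_visit: 620.00
  community_mh: 155.00
wage_rate_paid: 180.00
wage_rate_unpaid: 90.00
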