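# Switzerland — healthcare-system perspective inputs (USD).
# Fluorouracil is priced per 500 mg pack in the Swiss list.
country: Switzerland
drug_prices:
  pembrolizumab: {vial_mg: 100.0, usd_per_vial: 5399.28}
  gemcitabine: {vial_mg: 200.0, usd_per_vial: 41.36}
  cisplatin: {vial_mg: 10.0, usd_per_vial: 35.53}
  fluorouracil: {vial_mg: 500.0, usd_per_vial: 15.55}
  leucovorin: {vial_mg: 100.0, usd_per_vial: 45.01}
  oxaliplatin: {vial_mg: 50.0, usd_per_vial: 112.03}
ae_costs:
  neutropenia: 6845.62
  leukopenia: 9307.84
  thrombocytopenia: 6845.62
  anemia: 6845.62
ae_prob_pem:
  neutropenia: 0.47
  leukopenia: 0.12
  thrombocytopenia: 0.16
  anemia: 0.24
ae_prob_chem:
  neutropenia: 0.46
  leukopenia: 0.09
  thrombocytopenia: 0.18
  anemia: 0.25
examination_cost: 659.79
administration_cost: 1198.83
bsc_cost: 249.82
eol_cost: 14101.41
u_pfs: 0.80
u_pd: 0.73
bsa: 1.93
discount_rate: 0.03
wtp: 112250.0
second_line_prop_pem: 0.47
second_line_prop_chem: 0.49
io_prop_pem: 0.009
io_prop_chem: 0.011
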