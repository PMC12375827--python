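# Japan — healthcare-system perspective inputs (USD).
# Cisplatin is priced per 50 mg pack in the Japanese price list.
# Exchange-rate metadata only, never applied in computation: $1 = 152.25 JPY.
country: Japan
drug_prices:
  pembrolizumab: {vial_mg: 100.0, usd_per_vial: 1408.85}
  gemcitabine: {vial_mg: 200.0, usd_per_vial: 6.11}
  cisplatin: {vial_mg: 50.0, usd_per_vial: 22.09}
  fluorouracil: {vial_mg: 250.0, usd_per_vial: 1.58}
  leucovorin: {vial_mg: 100.0, usd_per_vial: 2.99}
  oxaliplatin: {vial_mg: 50.0, usd_per_vial: 18.10}
ae_costs:
  neutropenia: 244.62
  leukopenia: 163.03
  thrombocytopenia: 803.63
  anemia: 15.00
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
examination_cost: 115.67
administration_cost: 620.00
bsc_cost: 79.85
eol_cost: 12628.56
u_pfs: 0.73
u_pd: 0.69
bsa: 1.73
discount_rate: 0.03
wtp: 49261.0
second_line_prop_pem: 0.47
second_line_prop_chem: 0.49
io_prop_pem: 0.009
io_prop_chem: 0.011
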