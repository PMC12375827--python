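# China — healthcare-system perspective inputs (USD).
# Exchange-rate metadata only, never applied in computation: $1 = 7.1179 CNY.
country: China
drug_prices:
  pembrolizumab: {vial_mg: 100.0, usd_per_vial: 2517.32}
  gemcitabine: {vial_mg: 200.0, usd_per_vial: 8.43}
  cisplatin: {vial_mg: 10.0, usd_per_vial: 2.42}
  fluorouracil: {vial_mg: 250.0, usd_per_vial: 8.35}
  leucovorin: {vial_mg: 100.0, usd_per_vial: 3.66}
  oxaliplatin: {vial_mg: 50.0, usd_per_vial: 53.84}
ae_costs:
  neutropenia: 354.00
  leukopenia: 466.00
  thrombocytopenia: 1814.00
  anemia: 541.00
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
examination_cost: 55.60
administration_cost: 110.20
bsc_cost: 337.50
eol_cost: 2299.00
u_pfs: 0.76
u_pd: 0.68
bsa: 1.72
discount_rate: 0.05
wtp: 37663.0
second_line_prop_pem: 0.47
second_line_prop_chem: 0.49
io_prop_pem: 0.009
io_prop_chem: 0.011
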