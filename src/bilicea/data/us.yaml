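# United States — healthcare-system perspective inputs (USD).
country: US
drug_prices:
  pembrolizumab: {vial_mg: 100.0, usd_per_vial: 5342.15}
  gemcitabine: {vial_mg: 200.0, usd_per_vial: 4.00}
  cisplatin: {vial_mg: 10.0, usd_per_vial: 3.20}
  fluorouracil: {vial_mg: 250.0, usd_per_vial: 2.10}
  leucovorin: {vial_mg: 100.0, usd_per_vial: 8.31}
  oxaliplatin: {vial_mg: 50.0, usd_per_vial: 6.00}
ae_costs:
  neutropenia: 5321.00
  leukopenia: 5321.00
  thrombocytopenia: 6325.00
  anemia: 4953.00
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
examination_cost: 851.00
administration_cost: 324.00
bsc_cost: 523.48
eol_cost: 7894.00
u_pfs: 0.76
u_pd: 0.68
bsa: 1.86
discount_rate: 0.03
wtp: 229044.0
second_line_prop_pem: 0.47
second_line_prop_chem: 0.49
io_prop_pem: 0.009
io_prop_chem: 0.011
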