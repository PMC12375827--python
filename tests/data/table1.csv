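section,item,China,Japan,US,Switzerland
vial_mg,pembrolizumab,100,100,100,100
vial_mg,gemcitabine,200,200,200,200
vial_mg,cisplatin,10,50,10,10
vial_mg,fluorouracil,250,250,250,500
vial_mg,leucovorin,100,100,100,100
vial_mg,oxaliplatin,50,50,50,50
drug_price,pembrolizumab,2517.32,1408.85,5342.15,5399.28
drug_price,gemcitabine,8.43,6.11,4.00,41.36
drug_price,cisplatin,2.42,22.09,3.20,35.53
drug_price,fluorouracil,8.35,1.58,2.10,15.55
drug_price,leucovorin,3.66,2.99,8.31,45.01
drug_price,oxaliplatin,53.84,18.10,6.00,112.03
ae_cost,neutropenia,354.00,244.62,5321.00,6845.62
ae_cost,leukopenia,466.00,163.03,5321.00,9307.84
ae_cost,thrombocytopenia,1814.00,803.63,6325.00,6845.62
ae_cost,anemia,541.00,15.00,4953.00,6845.62
other,examination_cost,55.60,115.67,851.00,659.79
other,administration_cost,110.20,620.00,324.00,1198.83
other,bsc_cost,337.50,79.85,523.48,249.82
other,eol_cost,2299.00,12628.56,7894.00,14101.41
utility,u_pfs,0.76,0.73,0.76,0.80
utility,u_pd,0.68,0.69,0.68,0.73
other,bsa,1.72,1.73,1.86,1.93
other,discount_rate,0.05,0.03,0.03,0.03
other,wtp,37663,49261,229044,112250
ae_prob_pem,neutropenia,0.47,0.47,0.47,0.47
ae_prob_pem,leukopenia,0.12,0.12,0.12,0.12
ae_prob_pem,thrombocytopenia,0.16,0.16,0.16,0.16
ae_prob_pem,anemia,0.24,0.24,0.24,0.24
ae_prob_chem,neutropenia,0.46,0.46,0.46,0.46
ae_prob_chem,leukopenia,0.09,0.09,0.09,0.09
ae_prob_chem,thrombocytopenia,0.18,0.18,0.18,0.18
ae_prob_chem,anemia,0.25,0.25,0.25,0.25
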