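regimen,agent,cost_per_mg_eur,dose_mg_per_m2,days_per_cycle,published_cost_per_cycle_eur
AZA,azacitidine,3.40,75,7,3028.14
LDC,cytarabine,0.0271,150,7,48.38
SDC_cytarabine_idarubicin,cytarabine,0.0271,1000,7,322.56
SDC_cytarabine_idarubicin,idarubicin,10.52,12,3,642.60
SDC_cytarabine_mitoxantrone,cytarabine,0.0271,1000,7,322.56
SDC_cytarabine_mitoxantrone,mitoxantrone,3.62,12,3,220.99
SDC_cytarabine_daunorubicin,cytarabine,0.0271,1000,7,322.56
SDC_cytarabine_daunorubicin,daunorubicin,0.179,60,3,54.56
SDC_cytarabine_idarubicin_etoposide,cytarabine,0.0271,1000,4,184.32
SDC_cytarabine_idarubicin_etoposide,idarubicin,10.52,12,3,642.60
SDC_cytarabine_idarubicin_etoposide,etoposide,0.043,100,3,21.76
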