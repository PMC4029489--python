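arm,state,component,cost_eur
AZA,mds_on,premedication,0.70
AZA,mds_on,administration,442.40
AZA,mds_on,pharmacology,3028.14
AZA,mds_on,follow_up,238.55
AZA,mds_on,transfusions,926.07
AZA,mds_on,concurrent_medication,37.90
AZA,mds_on,routine_tests,237.49
BSC,mds_on,premedication,0
BSC,mds_on,administration,0
BSC,mds_on,pharmacology,0
BSC,mds_on,follow_up,238.55
BSC,mds_on,transfusions,1070.31
BSC,mds_on,concurrent_medication,54.72
BSC,mds_on,routine_tests,62.63
LDC,mds_on,premedication,2.11
LDC,mds_on,administration,380.20
LDC,mds_on,pharmacology,48.38
LDC,mds_on,follow_up,238.55
LDC,mds_on,transfusions,1754.35
LDC,mds_on,concurrent_medication,65.86
LDC,mds_on,routine_tests,181.74
SDC,mds_on,premedication,0
SDC,mds_on,administration,16344.02
SDC,mds_on,pharmacology,790.41
SDC,mds_on,follow_up,0
SDC,mds_on,transfusions,2557.71
SDC,mds_on,concurrent_medication,87.21
SDC,mds_on,routine_tests,1073.74
AZA,mds_off,follow_up,238.55
AZA,mds_off,transfusions,926.07
AZA,mds_off,concurrent_medication,54.72
AZA,mds_off,routine_tests,62.63
AZA,mds_off,annualized_ae_bsc,345.81
AZA,mds_off,administration_bsc,0
BSC,mds_off,follow_up,238.55
BSC,mds_off,transfusions,1070.31
BSC,mds_off,concurrent_medication,54.72
BSC,mds_off,routine_tests,62.63
BSC,mds_off,annualized_ae_bsc,345.81
BSC,mds_off,administration_bsc,0
LDC,mds_off,follow_up,238.55
LDC,mds_off,transfusions,1754.35
LDC,mds_off,concurrent_medication,54.72
LDC,mds_off,routine_tests,62.63
LDC,mds_off,annualized_ae_bsc,345.81
LDC,mds_off,administration_bsc,0
SDC,mds_off,follow_up,238.55
SDC,mds_off,transfusions,2557.71
SDC,mds_off,concurrent_medication,54.72
SDC,mds_off,routine_tests,62.63
SDC,mds_off,annualized_ae_bsc,345.81
SDC,mds_off,administration_bsc,0
AZA,aml,follow_up,233.33
AZA,aml,adverse_events,345.81
AZA,aml,concurrent_medication,132.18
AZA,aml,transfusions,1070.31
AZA,aml,routine_tests,70.24
BSC,aml,follow_up,233.33
BSC,aml,adverse_events,345.81
BSC,aml,concurrent_medication,132.18
BSC,aml,transfusions,1070.31
BSC,aml,routine_tests,70.24
LDC,aml,follow_up,233.33
LDC,aml,adverse_events,345.81
LDC,aml,concurrent_medication,132.18
LDC,aml,transfusions,1070.31
LDC,aml,routine_tests,70.24
SDC,aml,follow_up,233.33
SDC,aml,adverse_events,345.81
SDC,aml,concurrent_medication,132.18
SDC,aml,transfusions,1070.31
SDC,aml,routine_tests,70.24
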