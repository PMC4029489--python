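resource,category,cost_eur,description
inpatient_day,resource,742.91,standard length of stay 28 days
haematologist_visit,resource,62.22,standard MDS visit
nurse_visit,resource,33.20,average cost
biochemical_profile,test,44.03,average cost
bone_marrow_aspirate,test,133.80,average cost
full_blood_count,test,6.08,average cost
platelet_transfusion,transfusion,352.81,per unit
blood_transfusion,transfusion,353.23,per unit
neutropenia,adverse_event,68,medical visit and analytics
leucopenia,adverse_event,68,medical visit and analytics
febrile_neutropenia,adverse_event,3735,DRG simple pneumonia and pleurisy
pyrexia,adverse_event,3735,DRG simple pneumonia and pleurisy
pneumonia,adverse_event,3735,DRG simple pneumonia and pleurisy
sepsis,adverse_event,3728,ICD 205.00
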