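improvement_id,name,scenario_label,additional_treated,nnt,benefit_score,phb_gain,implementation_cost,offset_savings,net_cost,rank_printed,cost_ratio_printed,cost_phb_ratio_printed,recommended_flag,consistency_flag
vw_effective_use,More effective use of the virtual ward,base,,,,20212,,,-385821,1,1.91,-19.09,true,true
proactive_case_finding,Proactive case finding,most optimistic scenario,,,,93075,,,-639803,2,7.3,-6.87,true,true
pr_uptake,Increasing uptake of PR,online offering,,,,18000,,,-11874,3,4.87,-0.66,true,true
mindsong_kiactiv,Improving uptake to Mindsong and KiActiv,base,,,,6390,,,-2491,4,NA,-0.39,true,true
vba_tobacco,VBA for tobacco dependency,base,,,,12960,,,-399,5,1.06,-0.03,true,true
vaping_pilot,Vaping as a harm reduction pilot,non-quitters,,,,41515,,,13687,6,0.15,0.33,false,true
vaping_pilot,Vaping as a harm reduction pilot,10% uptake,,,,743850,,,245532,6,0.32,0.33,false,true
pneumonia_vaccination,Improving uptake of pneumonia vaccinations,base,,,,34200,,,16082,7,0.56,0.47,false,true
mpt_management,MPT management of patients,1 PCN,,,,54320,,,101559,8,NA,1.87,false,true
mpt_management,MPT management of patients,2 PCNs,,,,90440,,,203118,9,NA,2.25,false,true
proactive_case_finding,Proactive case finding,least optimistic scenario,,,,5475,,,12919,10,0.77,2.36,false,true
mpt_management,MPT management of patients,3 PCNs,,,,116830,,,304677,11,NA,2.61,false,true
smoking_cessation_uptake,Increasing uptake of smoking cessation services,base,,,,107800,,,323060,12,0.02,3,false,true
fuel_poverty,Avoiding fuel poverty,10% increase,,,,1350,,,9000,13,NA,6.67,false,true
fuel_poverty,Avoiding fuel poverty,20% increase,,,,3420,,,22800,13,NA,6.67,false,true
fuel_poverty,Avoiding fuel poverty,50% increase,,,,6750,,,45000,13,NA,6.67,false,true
psych_support_primary,Psychological support for patients in primary care,10% uptake,,,,46050,,,366864,14,0.03,7.97,false,true
psych_support_primary,Psychological support for patients in primary care,25% uptake,,,,115200,,,917845,14,0.03,7.97,false,true
psych_support_primary,Psychological support for patients in primary care,50% uptake,,,,230400,,,1835823,14,0.03,7.97,false,true
pr_uptake,Increasing uptake of PR,improving completion rates in the current services,,,,23490,,,266273,15,0.07,11.34,false,true
pr_uptake,Increasing uptake of PR,improving uptake through the standard route,,,,18000,,,271255,16,-0.05,15.07,false,true
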