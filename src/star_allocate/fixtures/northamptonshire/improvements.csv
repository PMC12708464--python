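improvement_id,name,scenario_label,additional_treated,nnt,benefit_score,phb_gain,implementation_cost,offset_savings,net_cost,rank_printed,cost_ratio_printed,cost_phb_ratio_printed,recommended_flag,consistency_flag
post_exacerbation_support,Post-exacerbation support,base,,,,12880,,,-46757,1,1.15,-0.28,true,false
group_consultations,Reducing unwarranted variation in primary care yearly reviews through group consultations,10% uptake,,,,79200,,,-179,2,1,0,true,true
group_consultations,Reducing unwarranted variation in primary care yearly reviews through group consultations,25% uptake,,,,198780,,,-14,2,1,0,true,true
group_consultations,Reducing unwarranted variation in primary care yearly reviews through group consultations,50% uptake,,,,397440,,,-29,2,1,0,true,true
mycopd_launch,Launch of myCOPD app,base,,,,367850,,,3832,3,inf,0.01,true,true
vba_primary_care,VBA in primary care,base,,,,6525,,,1956,4,0.7,0.29,true,false
info_centres,Improved signposting to services through information centres,base,,,,100904,,,47433,5,0.41,0.47,false,true
spirometry_capacity,Increasing capacity in spirometry testing,base,,,,60760,,,33973,6,0.91,0.56,false,true
smoking_cessation_uptake,Increasing uptake of smoking cessation services,increasing capacity,,,,83525,,,254493,7,0.15,3.05,false,true
smoking_cessation_uptake,Increasing uptake of smoking cessation services,standardised referral pathways,,,,21450,,,85964,8,0.14,4.01,false,true
pr_expansion,Expansion of PR services,base,,,,1932,,,25836,9,0.08,13.37,false,true
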