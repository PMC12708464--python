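improvement_id,name,scenario_label,additional_treated,nnt,benefit_score,phb_gain,implementation_cost,offset_savings,net_cost,rank_printed,cost_ratio_printed,cost_phb_ratio_printed,recommended_flag,consistency_flag
palliative_hospice_vw,Expanding palliative care through hospice-at-home virtual ward,vs hospice care,,,,10675,,,-11312029,1,27.86,-1059.67,false,true
vw_early_discharge,Virtual ward as early discharge support,base,,,,48930,,,-1802830,2,2.08,-36.85,true,true
spirometry_uptake,Increasing uptake and quality of spirometry testing,doubling tests in primary care,,,,30675,,,-134401,3,1.89,-4.38,true,true
spirometry_uptake,Increasing uptake and quality of spirometry testing,expanding RDHs,,,,43575,,,-163743,4,2.23,-3.76,true,true
mycopd_selfcare,Promoting self-care through the myCOPD app,base,,,,450680,,,5868,5,NA,0.01,true,true
smoking_cessation_uptake,Increasing uptake of smoking cessation services,tertiary prevention - Quit with Bella app,,,,143370,,,33474,6,0.71,0.23,true,true
social_prescribing_pa,Promoting respiratory services within localities through social prescribing - physical activity,10% uptake,,,,116220,,,30016,7,0.68,0.26,true,true
social_prescribing_pa,Promoting respiratory services within localities through social prescribing - physical activity,25% uptake,,,,290615,,,77551,7,0.68,0.26,true,false
social_prescribing_pa,Promoting respiratory services within localities through social prescribing - physical activity,50% uptake,,,,581360,,,155143,7,0.68,0.26,true,false
smoking_cessation_uptake,Increasing uptake of smoking cessation services,primary prevention - Quit with Bella app,,,,13900,,,7508,8,0.25,0.54,true,true
primary_care_education,Improving the quality of primary care management through clinical education,base,,,,139640,,,167064,9,NA,1.2,false,true
pneumonia_vaccination,Driving pneumonia vaccination uptake,base,,,,188325,,,489078,10,0.19,2.6,false,true
pr_uptake,Increasing uptake of PR services,increasing completion rate to 75%,,,,33286,,,145254,11,0.16,4.36,false,true
pr_uptake,Increasing uptake of PR services,double people starting the course,,,,22606,,,155218,12,0.11,6.87,false,true
psychological_support,Psychological support,10% uptake,,,,88050,,,766497,13,0.08,8.71,false,true
psychological_support,Psychological support,25% uptake,,,,220050,,,1919475,13,0.08,8.71,false,false
psychological_support,Psychological support,50% uptake,,,,440100,,,3836326,13,0.08,8.71,false,false
palliative_hospice_vw,Expanding palliative care through hospice-at-home virtual ward,vs GP palliative care,,,,10675,,,133944,14,0.68,12.55,false,true
smoking_cessation_uptake,Increasing uptake of smoking cessation services,primary prevention - smoking cessation service,,,,390100,,,5561830,15,0.01,14.26,false,true
smoking_cessation_uptake,Increasing uptake of smoking cessation services,tertiary prevention - smoking cessation service,,,,210690,,,3250792,16,0.04,15.43,false,true
vw_admissions_avoidance,Virtual ward admissions avoidance,10% uptake,,,,11445,,,504054,17,NA,44.04,false,true
vw_admissions_avoidance,Virtual ward admissions avoidance,25% uptake,,,,28595,,,1217036,17,NA,42.56,false,true
vw_admissions_avoidance,Virtual ward admissions avoidance,50% uptake,,,,57190,,,24405820,17,NA,42.07,false,false
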