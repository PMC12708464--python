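improvement_id,name,scenario_label,additional_treated,nnt,benefit_score,phb_gain,implementation_cost,offset_savings,net_cost,rank_printed,cost_ratio_printed,cost_phb_ratio_printed,recommended_flag,consistency_flag
targeted_screening,Improving case-finding by targeted COPD screening,most optimistic scenario,,,,254505,,,-1344055,1,3.8,-5.28,true,true
targeted_screening,Improving case-finding by targeted COPD screening,least optimistic scenario,,,,56430,,,-196521,2,1.94,-3.48,true,true
making_every_contact_count,Making every contact count,base,,,,23814,,,-2489,3,1.2,-0.1,true,true
group_consultations,Conducting patients' yearly reviews through group consultations,10% uptake,,,,206040,,,32,4,1,0,false,true
group_consultations,Conducting patients' yearly reviews through group consultations,25% uptake,,,,516290,,,30,4,1,0,false,true
group_consultations,Conducting patients' yearly reviews through group consultations,50% uptake,,,,1032580,,,61,4,1,0,false,true
breathe_easy_referral,Introducing a referral pathway to Breathe Easy groups,10% uptake,,,,1116,,,559,5,NA,0.5,false,true
breathe_easy_referral,Introducing a referral pathway to Breathe Easy groups,25% uptake,,,,2728,,,1365,5,NA,0.5,false,true
breathe_easy_referral,Introducing a referral pathway to Breathe Easy groups,50% uptake,,,,5456,,,2731,5,NA,0.5,false,true
smoking_cessation_uptake,Improving uptake to smoking cessation services,increasing uptake to meet the 5% NICE target,,,,102628,,,69018,6,0.47,0.67,false,true
smoking_cessation_uptake,Improving uptake to smoking cessation services,doubling the number of people with COPD who set quit dates,,,,106624,,,76403,7,0.45,0.72,false,true
intent_schools,Expanding the INTENT smoking prevention programme in schools,base,,,,140200,,,203758,8,0.29,1.45,false,true
post_pr_exercise,Offering a post-PR exercise course,10% uptake,,,,8100,,,19800,9,NA,2.44,false,true
post_pr_exercise,Offering a post-PR exercise course,25% uptake,,,,20250,,,49500,9,NA,2.44,false,true
post_pr_exercise,Offering a post-PR exercise course,50% uptake,,,,40490,,,99220,9,NA,2.44,false,false
pr_access_expansion,Expanding access to pulmonary rehabilitation,MRC 3+,,,,366480,,,3222846,10,0.09,8.79,false,true
pr_access_expansion,Expanding access to pulmonary rehabilitation,MRC 2+,,,,91440,,,806954,10,0.09,8.79,false,false
affordable_warmth,Expanding affordable warmth schemes,x2 expansion,,,,2535,,,92468,11,NA,36.48,false,true
affordable_warmth,Expanding affordable warmth schemes,x4 expansion,,,,7605,,,277403,11,NA,36.48,false,true
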