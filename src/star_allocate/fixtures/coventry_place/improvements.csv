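improvement_id,name,scenario_label,additional_treated,nnt,benefit_score,phb_gain,implementation_cost,offset_savings,net_cost,rank_printed,cost_ratio_printed,cost_phb_ratio_printed,recommended_flag,consistency_flag
vw_expansion,Expansion of the virtual ward,base,,,,24820,,,-553523,1,2.72,-22.3,true,true
spirometry_targeting,Targeting spirometry testing and improving uptake,improving the diagnosis rate to 56.28%,,,,39690,,,-171982,2,3.44,-4.33,true,true
spirometry_targeting,Targeting spirometry testing and improving uptake,improving the diagnosis rate to 35%,,,,24696,,,-80714,3,2.15,-3.27,true,true
spirometry_targeting,Targeting spirometry testing and improving uptake,increasing capacity to meet demand,,,,19894,,,-52051,4,1.74,-2.62,true,true
spirometry_targeting,Targeting spirometry testing and improving uptake,expanding TLHCs,,,,10192,,,-26258,5,1.72,-2.58,true,true
joint_clinics,Joint clinics in primary care,current establishment of 5.6 RNSs,,,,174604,,,37714,6,0.56,0.22,true,true
copd_education_package,Education package for people with COPD,base,,,,65520,,,33251,7,NA,0.51,true,true
joint_clinics,Joint clinics in primary care,with 8.6 RNSs,,,,447128,,,381796,8,-1.05,0.85,true,true
schools_education,Education in schools against smoking and vaping,base,,,,97700,,,107939,9,0.41,1.1,true,true
carer_support,Carer support,base,,,,4800,,,10080,10,NA,2.1,false,true
awareness_campaign,Targeted awareness campaign,base,,,,24946,,,143629,11,0.46,5.76,false,true
smoking_innovation,Innovation in smoking cessation services,increasing capacity in Healthy Lifestyles service,,,,140032,,,1372001,12,0.08,9.8,false,true
smoking_innovation,Innovation in smoking cessation services,improving quit rates in GP- and pharmacy-led services,,,,10192,,,189478,13,0.04,18.59,false,true
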