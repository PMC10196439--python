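label,population,dose_mg,dose_ug_per_kg,prandial,n,prop_female,age_lo,age_hi,matrix,cmax_ng_per_ml,tmax_h,auc_ng_h_per_ml,auc_type,t_half_h
hv_6mg,healthy_volunteer,6,,fasted,12,0.0,18,45,plasma,18.3,3.9,347,auc_0_72,
hv_12mg,healthy_volunteer,12,,fasted,12,0.0,18,45,plasma,30.6,3.8,513,auc_0_72,
hv_15mg,healthy_volunteer,15,,fasted,12,0.0,18,45,plasma,48.5,3.8,820,auc_0_72,
hv_30mg,healthy_volunteer,30,,fasted,12,0.485,18,45,plasma,84.8,4.6,1724,auc_0_72,20.1
hv_200ugkg_munoz,healthy_volunteer,,200,fasted,57,0.60,18,59,plasma,43.2,4.2,1088,auc_0_72,80.7
oncho_150ugkg_nigeria,black_african_adult,,150,fasted,12,0.33,18,50,plasma,38.2,4.7,1545,auc_0_72,56.5
oncho_150ugkg_sudan,black_african_adult,,150,fasted,10,0.0,18,50,plasma,38.0,5.6,1032,auc_0_72,16.0
adult_200ugkg_dbs_study,healthy_volunteer,,200,fasted,11,0.5,18,50,plasma,51.6,3.9,987,auc_0_inf,26.2
psac_200ugkg,african_pediatric,,200,fasted,39,0.5,2,5,dbs,31.5,5.9,610,auc_0_inf,16.3
psac_100ugkg,african_pediatric,,100,fasted,41,0.5,2,5,dbs,20.0,6.0,378,auc_0_inf,17.3
sac_200ugkg,african_pediatric,,200,fasted,41,0.5,6,12,dbs,28.3,6.0,808,auc_0_inf,18.1
sac_400ugkg,african_pediatric,,400,fasted,39,0.5,6,12,dbs,52.5,6.0,1288,auc_0_inf,18.1
sac_600ugkg,african_pediatric,,600,fasted,40,0.5,6,12,dbs,85.3,6.0,2237,auc_0_inf,18.1
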