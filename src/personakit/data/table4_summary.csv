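variable,category,all_n,all_pct,c1_n,c1_pct,c2_n,c2_pct,c3_n,c3_pct,c4_n,c4_pct,c5_n,c5_pct,supp_n,supp_pct,erratum
age_group,18-39,292,26,68,25,97,43,7,2.3,0,0,120,48,5,63,
age_group,40-59,344,31,133,49,68,30,36,12,17,30,90,36,1,13,
age_group,60+,467,42,71,26,58,26,259,86,40,70,39,16,2,25,
sex,Female,649,59,163,60,128,57,164,54,44,77,150,60,0,0,
sex,Male,454,41,109,40,95,43,138,46,13,23,99,40,0,0,
sex,Nonbinary,0,0,0,0,0,0,0,0,0,0,0,0,5,63,
sex,Transgender,0,0,0,0,0,0,0,0,0,0,0,0,3,38,
race_ethnicity,White,832,75,201,74,156,70,251,83,48,84,176,71,5,63,
race_ethnicity,Black,28,2.5,3,1.1,8,3.6,5,1.7,1,1.8,11,4.4,0,0,
race_ethnicity,Hispanic,57,5.2,12,4.4,18,8.1,8,2.6,0,0,19,7.6,1,13,
race_ethnicity,Asian,82,7.4,30,11,21,9.4,13,4.3,4,7,14,5.6,1,13,
race_ethnicity,Other,104,9.4,26,9.6,20,9,25,8.3,4,7,29,12,1,13,
region,Eastern,205,19,37,14,35,16,69,23,9,16,55,22,1,13,
region,Western,898,81,235,86,188,84,233,77,48,84,194,78,7,88,
english_only,Only English,969,88,230,85,191,86,281,93,53,93,214,86,8,100,
english_only,Other language,134,12,42,15,32,14,21,7,4,7,35,14,0,0,
parental_status,Parent,271,25,83,31,60,27,23,7.6,7,12,98,39,0,0,
parental_status,Not a parent,832,75,189,69,163,73,279,92,50,88,151,61,8,100,
education,4-year degree or more,657,60,207,76,146,65,123,41,38,67,143,57,6,75,
education,2-year or some college,290,26,53,19,58,26,101,33,15,26,63,25,1,13,
education,High school graduate,123,11,11,4,18,8.1,58,19,4,7,32,13,1,13,
education,Less than high school,33,3,1,0.4,1,0.4,20,6.6,0,0,11,4.4,0,0,
tech_readiness,Higher,826,75,256,94,219,98,97,32,13,23,241,97,8,100,
tech_readiness,Lower,277,25,15,5.9,4,1.8,205,68,44,77,8,3.2,0,0,c1
waverify_referral,Referral,223,20,136,50,26,12,17,5.6,10,18,34,14,1,13,
waverify_referral,News,144,13,53,19,11,4.9,31,10,27,47,22,8.8,0,0,
waverify_referral,Health care,117,11,62,23,19,8.5,19,6.3,3,5.3,14,5.6,0,0,
waverify_referral,Other,47,4.3,17,6.3,11,4.9,8,2.6,3,5.3,8,3.2,1,13,
waverify_referral,Never heard,572,52,4,1.5,156,70,227,75,14,25,171,69,6,75,
waverify_usage,Yes,276,25,234,86,5,2.2,21,7,7,12,9,3.6,1,13,
waverify_usage,Willing,560,51,17,6.3,193,87,150,50,38,67,162,65,6,75,
waverify_usage,Not willing,267,24,21,7.7,25,11,131,43,12,21,78,31,1,13,
covid_policy_opinion,Oppose,226,20,26,9.6,27,12,69,23,8,14,96,39,0,0,
covid_policy_opinion,Support,877,80,246,90,196,88,233,77,49,86,153,61,8,100,
health_portal,Yes,949,86,262,96,212,95,199,66,57,100,219,88,7,88,
wa_notify,Yes,535,49,235,86,223,100,28,9.3,49,86,0,0,2,29,supp
tracking,Yes,660,60,209,77,181,81,24,7.9,45,79,201,81,6,75,
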