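age_group,sex,race_ethnicity,survey_count,cluster_count,oe_printed,marked,erratum
18-39,Female,All,182,46,102,0,0
18-39,Female,White,106,27,103,0,0
18-39,Female,Black,8,2,101,0,0
18-39,Female,Hispanic,25,5,81,0,0
18-39,Female,Asian,18,6,97,0,1
18-39,Female,Other,25,6,97,0,0
18-39,Male,All,110,22,81,0,0
18-39,Male,White,67,12,73,0,0
18-39,Male,Black,2,0,0,0,0
18-39,Male,Hispanic,6,2,135,0,0
18-39,Male,Asian,19,5,107,0,0
18-39,Male,Other,16,3,76,0,0
40-59,Female,All,208,74,144,0,0
40-59,Female,White,155,53,139,0,0
40-59,Female,Black,5,0,0,0,0
40-59,Female,Hispanic,16,4,101,0,0
40-59,Female,Asian,19,11,235,1,0
40-59,Female,Other,13,6,187,0,0
40-59,Male,All,136,59,176,0,0
40-59,Male,White,106,49,187,1,0
40-59,Male,Black,5,1,81,0,0
40-59,Male,Hispanic,2,1,203,0,0
40-59,Male,Asian,11,4,147,0,0
40-59,Male,Other,12,4,135,0,0
60+,Female,All,259,43,67,0,0
60+,Female,White,225,38,68,0,0
60+,Female,Black,1,0,0,0,0
60+,Female,Hispanic,7,0,0,0,0
60+,Female,Asian,4,1,101,0,0
60+,Female,Other,22,4,74,0,0
60+,Male,All,208,28,55,0,0
60+,Male,White,173,22,52,0,0
60+,Male,Black,7,0,0,0,0
60+,Male,Hispanic,1,0,0,0,0
60+,Male,Asian,11,3,111,0,0
60+,Male,Other,16,3,76,0,0
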