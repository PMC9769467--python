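variable,category,SUEP_original,POP_original,HAP_original,SUEP_anonymized,POP_anonymized,HAP_anonymized
age_group,<=17,40,0,0,0,0,0
age_group,18-39,317,920,78,275,917,0
age_group,40-59,609,967,230,541,957,129
age_group,60-79,584,412,187,528,394,108
age_group,>=80,147,35,23,43,12,0
age_group,unknown/missing,0,12,1,0,0,0
gender,male,1020,1040,352,868,1001,181
gender,female,677,1305,166,519,1279,56
gender,diverse,0,0,0,0,0,0
gender,unknown/missing,0,1,1,0,0,0
quarter_year,Q1 2020,2,554,11,0,541,0
quarter_year,Q2 2020,0,279,24,0,271,0
quarter_year,Q3 2020,7,275,19,0,265,0
quarter_year,Q4 2020,68,748,61,0,740,0
quarter_year,Q1 2021,534,367,156,496,365,130
quarter_year,Q2 2021,397,86,108,390,76,85
quarter_year,Q3 2021,208,1,39,194,0,0
quarter_year,Q4 2021,357,1,72,307,0,22
quarter_year,Q1 2022,66,0,7,0,0,0
quarter_year,unknown/missing,58,35,22,0,22,0
most_severe_phase,mild,191,2185,0,149,2131,0
most_severe_phase,moderate,1135,124,320,919,114,144
most_severe_phase,severe,349,37,199,307,35,93
most_severe_phase,unknown/missing,22,0,0,12,0,0
patient_status_end_acute,ambulant,192,2108,0,149,2069,0
patient_status_end_acute,discharged,1084,124,407,911,112,180
patient_status_end_acute,referral/transfer,221,0,26,176,0,14
patient_status_end_acute,dead,103,0,62,87,0,34
patient_status_end_acute,unknown/missing,97,114,23,64,99,9
hospitalization,yes,1502,161,519,1238,149,237
hospitalization,no,192,2185,0,149,2131,0
hospitalization,unknown/missing,3,0,0,0,0,0
intensive_care,yes,403,33,200,356,31,99
intensive_care,no,1294,2313,319,1031,2249,138
intensive_care,unknown/missing,0,0,0,0,0,0
invasive_ventilation,yes,153,18,111,128,18,60
invasive_ventilation,no,1522,2328,327,1245,2262,131
invasive_ventilation,unknown/missing,22,0,81,14,0,46
followup_3m_available,yes,968,2346,158,859,2280,103
followup_3m_available,no/not yet,729,0,361,528,0,134
ability_to_work_3m,yes,454,1754,41,442,1729,30
ability_to_work_3m,no,89,126,91,85,124,59
ability_to_work_3m,unknown/missing,425,466,26,332,427,14
any_symptom_3m,yes,305,900,43,280,874,36
any_symptom_3m,no,663,862,115,579,847,67
any_symptom_3m,unknown/missing,0,584,0,0,559,0
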