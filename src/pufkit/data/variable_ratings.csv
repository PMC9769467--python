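variable,replicability,availability,distinguishability
age_group,3,3,3
gender,3,3,2
quarter_first_diagnosis,1,3,2
year_first_diagnosis,1,3,2
cohort,3,3,2
mild_phase,1,2,1
moderate_phase,1,2,2
severe_phase,1,2,2
patient_status_end_acute,1,2,2
hospitalization,1,2,2
intensive_care,1,2,2
invasive_ventilation,1,1,2
followup_3m_available,1,2,1
ability_to_work_3m,1,2,2
any_symptom_3m,1,1,2
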