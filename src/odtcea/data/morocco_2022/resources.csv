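resource,stable_per_month,outpt_relapse_per_event,hosp_relapse_per_event,eps_per_event,weight_gain_per_event,unit_cost_mad
hospital_day,0,0,11.7,0,0,1058.30
ambulatory_care_centre,0,1.25,1.25,0,0,5220.42
emergency_department,0,1,1,0,0,550.00
doctor_visit,1,1,1,1,0.5,571
psychiatric_clinic_visit,1.5,2,2,1,2.5,550
home_care_hour,0,2.75,2.75,0,0,854
group_counselling_hour,0.5,1.5,1.5,0,5,740
nutritionist_visit,0,0,0,0,2.5,250
extra_admission_day,0,0,0,0,0,265.00
other_medication,0,0,0,0,0,229
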