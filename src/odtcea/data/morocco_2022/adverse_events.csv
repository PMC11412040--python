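medication,eps_pct,weight_gain_pct,diabetes_pct
olanzapine_sot,16,30,3
risperidone_sot,25,14,3
aripiprazole_sot,2,17,2
olanzapine_odt,16,30,3
risperidone_odt,25,14,3
aripiprazole_odt,2,17,2
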