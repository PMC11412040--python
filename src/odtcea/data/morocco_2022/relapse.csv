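medication,category,hospitalized_pct,outpatient_pct
olanzapine_sot,compliant,2,2
olanzapine_sot,partial,4,3
olanzapine_sot,non,5,5
risperidone_sot,compliant,4,4
risperidone_sot,partial,6,6
risperidone_sot,non,9,9
aripiprazole_sot,compliant,5,5
aripiprazole_sot,partial,9,8
aripiprazole_sot,non,12,11
olanzapine_odt,compliant,2,2
olanzapine_odt,partial,4,3
olanzapine_odt,non,5,5
risperidone_odt,compliant,4,4
risperidone_odt,partial,6,6
risperidone_odt,non,9,9
aripiprazole_odt,compliant,5,5
aripiprazole_odt,partial,9,8
aripiprazole_odt,non,12,11
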