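medication,compliant_pct,partially_compliant_pct,non_compliant_pct
olanzapine_sot,23,43,34
risperidone_sot,21,39,40
aripiprazole_sot,19,35,46
olanzapine_odt,37,29,34
risperidone_odt,35,25,40
aripiprazole_odt,33,21,46
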