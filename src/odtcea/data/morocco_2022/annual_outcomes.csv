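group,stable_pct,hospitalized_pct,outpatient_pct
olanzapine,79,11,10
risperidone,62,19,19
aripiprazole,50,26,24
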