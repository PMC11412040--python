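strategy,total_cost_mad,total_qaly
olanzapine_odt,3034,0.7916
olanzapine_sot,3106,0.7733
risperidone_odt,3710,0.7850
risperidone_sot,3811,0.7666
aripiprazole_odt,3675,0.7822
aripiprazole_sot,3728,0.7633
olanzapine,6140,1.5650
risperidone,7521,1.5517
aripiprazole,7403,1.5456
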