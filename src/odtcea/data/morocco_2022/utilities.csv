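state,compliant,partial,non
stable,0.88,0.75,0.75
relapse_outpt,0.74,0.63,0.63
relapse_hosp,0.53,0.53,0.42
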