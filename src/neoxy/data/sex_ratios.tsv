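dam_karyomorph	n_dams	n_sons	n_offspring
KII	17	54	149
KIII	18	70	171
KIV	3	7	7
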