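karyomorph	n_females	n_gave_birth
KII	13	NA
KIII	15	NA
KIV	4	0
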