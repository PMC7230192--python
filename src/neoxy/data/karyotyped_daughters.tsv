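dam_karyomorph	daughters_KII	daughters_KIII	daughters_KIV
KII	9	25	3
KIII	21	6	0
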