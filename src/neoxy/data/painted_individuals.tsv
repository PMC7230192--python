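id	diploid_number	origin	sex_complement	lman2_type
LMAN0f	47	laboratory	neo-X1/neo-X2/neo-X3	2b2b
LMAN1f	47	laboratory	neo-X1/neo-X2/neo-X3	2b2b
LMAN2f	47	laboratory	neo-X1/neo-X2/neo-X3	2a2b
LMAN3f	47	laboratory	neo-X1/neo-X2/neo-X3	2a2b
LMAN5f	47	laboratory	neo-X2/neo-X3/neo-Y	2a2b
LMAN6f	47	laboratory	neo-X2/neo-X3/neo-Y	2a2a
LMAN10m	48	laboratory	neo-X1/neo-Y/neo-X3/neo-X3	2a2a
LMAN14f	47	wild	neo-X2/neo-X3/neo-Y	2a2c
LMAN15m	48	wild	neo-X1/neo-Y/neo-X3/neo-X3	2a2c
LMAN16f	47	wild	neo-X1/neo-X2/neo-X3	2a2a
LMAN17f	47	wild	neo-X1/neo-X2/neo-X3	2a2c
LMAN19f	47	wild	neo-X1/neo-X2/neo-X3	2c2c
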