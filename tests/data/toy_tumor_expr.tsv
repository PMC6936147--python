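sample	A	B	C	D	E	F
P1	5	0	3	1	0	2
P2	5	0	0	2	3	2
P3	5	3	0	3	0	2
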