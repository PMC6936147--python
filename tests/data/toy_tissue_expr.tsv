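sample	A	B	C	D	E	F
T1	1	2	1	1	5	1
T2	2	4	2	-1	5	3
T3	3	6	3	-1	5	2
T4	4	8	4	1	5	5
T5	5	10	5	1	5	4
T6	6	12	7	-1	5	6
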