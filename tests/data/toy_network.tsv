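A	B
A	C
B	C
C	D
D	E
E	F
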