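name	delta_formula	sign	z	n_M
[M+H]+	H	1	1	1
[M+NH4]+	NH4	1	1	1
[M+Na]+	Na	1	1	1
[M+K]+	K	1	1	1
[M+2H]2+	H2	1	2	1
[M-H]-	H	-1	-1	1
[M+HCOO]-	CHO2	1	-1	1
[M+Cl]-	Cl	1	-1	1
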