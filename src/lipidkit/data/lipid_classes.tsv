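class_code	base_formula	n_chains	c_min	c_max	db_min	db_max	adducts_pos	adducts_neg	internal_standard
CE	C27H44O2	1	14	40	0	8	[M+NH4]+,[M+Na]+		CE(16:0)-d7
LPC	C8H18NO7P	1	12	30	0	8	[M+H]+	[M+HCOO]-	LPC(14:0)
LPE	C5H12NO7P	1	12	30	0	8		[M-H]-	LPE(14:0)
LPE[O]	C5H14NO6P	1	12	30	0	8		[M-H]-	LPE(14:0)
LPE[P]	C5H12NO6P	1	12	30	0	8		[M-H]-	LPE(14:0)
LPA	C3H7O7P	1	12	26	0	6		[M-H]-	LPA(14:0)
LPG	C6H13O9P	1	12	26	0	6		[M-H]-	LPG(14:0)
LPI	C9H17O12P	1	12	26	0	6		[M-H]-	LPA(14:0)
FA	O2	1	12	36	0	8		[M-H]-	LPC(14:0)
PC	C8H16NO8P	2	26	56	0	12	[M+H]+	[M+HCOO]-	PC(28:0)
PC[O]	C8H18NO7P	2	26	46	0	8	[M+H]+		PC(28:0)
PE	C5H10NO8P	2	26	50	0	12		[M-H]-	PE(28:0)
PE[O]	C5H12NO7P	2	26	46	0	8		[M-H]-	PE(28:0)
PE[P]	C5H10NO7P	2	26	46	0	8		[M-H]-	PE(28:0)
PS	C6H10NO10P	2	28	46	0	8		[M-H]-	PS(28:0)
PG	C6H11O10P	2	28	44	0	8		[M-H]-	PG(28:0)
PA	C3H5O8P	2	28	44	0	8		[M-H]-	PA(28:0)
PI	C9H15O13P	2	28	44	0	8		[M-H]-	PI(16:0)
DG	C3H4O5	2	24	52	0	10	[M+NH4]+		DG(28:0)
SM[d]	C5H13N2O6P	2	28	48	0	6	[M+H]+		SM[d](30:1)
Cer[d]	HNO3	2	28	48	0	6	[M+H]+	[M-H]-	Cer[d](30:1)
Hex2Cer[d]	C12H21NO13	2	28	48	0	6	[M+H]+		SM[d](30:1)
SM4[d]	C6H11NO11S	2	28	48	0	6		[M-H]-	SM[d](30:1)
SM4[t]	C6H11NO12S	2	28	48	0	6		[M-H]-	SM[d](30:1)
GM1[d]	C37H61N3O31	2	30	44	0	4		[M-H]-	SM[d](30:1)
GM2[d]	C31H51N3O26	2	30	44	0	4		[M-H]-	SM[d](30:1)
GM3[d]	C23H38N2O21	2	30	44	0	4		[M-H]-	SM[d](30:1)
TG	C3H2O6	3	36	80	0	16	[M+NH4]+		TG(42:0)
CL	C9H14O17P2	4	48	80	0	12		[M-H]-	CL(56:0)
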