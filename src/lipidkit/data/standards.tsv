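name	formula	nmol
CL(56:0)	C65H126O17P2	0.1
PC(28:0)	C36H72NO8P	2.0
PG(28:0)	C34H67O10P	0.1
PS(28:0)	C34H66NO10P	5.0
PE(28:0)	C33H66NO8P	0.5
PA(28:0)	C31H61O8P	0.5
SM[d](30:1)	C35H71N2O6P	2.125
LPG(14:0)	C20H41O9P	0.02
LPE(14:0)	C19H40NO7P	0.1
LPC(14:0)	C22H46NO7P	0.5
LPA(14:0)	C17H35O7P	0.1
PI(16:0)	C25H47O13P	0.5
DG(28:0)	C31H60O5	0.5
TG(42:0)	C45H86O6	0.5
CE(16:0)-d7	C43H69D7O2	2.5
Cer[d](30:1)	C30H59NO3	0.125
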