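name	hemisphere	region	excluded
AF_left	left	supratentorial	0
AF_right	right	supratentorial	0
ATR_left	left	supratentorial	0
ATR_right	right	supratentorial	0
CA	commissural	supratentorial	0
CC	commissural	supratentorial	0
CC_1	commissural	supratentorial	0
CC_2	commissural	supratentorial	0
CC_3	commissural	supratentorial	0
CC_4	commissural	supratentorial	0
CC_5	commissural	supratentorial	0
CC_6	commissural	supratentorial	0
CC_7	commissural	supratentorial	0
CG_left	left	supratentorial	0
CG_right	right	supratentorial	0
CST_left	left	supratentorial	0
CST_right	right	supratentorial	0
MLF_left	left	supratentorial	0
MLF_right	right	supratentorial	0
FPT_left	left	supratentorial	0
FPT_right	right	supratentorial	0
FX_left	left	supratentorial	1
FX_right	right	supratentorial	1
ICP_left	left	infratentorial	0
ICP_right	right	infratentorial	0
IFO_left	left	supratentorial	0
IFO_right	right	supratentorial	0
ILF_left	left	supratentorial	0
ILF_right	right	supratentorial	0
MCP	commissural	infratentorial	0
OR_left	left	supratentorial	0
OR_right	right	supratentorial	0
POPT_left	left	supratentorial	0
POPT_right	right	supratentorial	0
SCP_left	left	infratentorial	0
SCP_right	right	infratentorial	0
SLF_I_left	left	supratentorial	0
SLF_I_right	right	supratentorial	0
SLF_II_left	left	supratentorial	0
SLF_II_right	right	supratentorial	0
SLF_III_left	left	supratentorial	0
SLF_III_right	right	supratentorial	0
STR_left	left	supratentorial	0
STR_right	right	supratentorial	0
UF_left	left	supratentorial	0
UF_right	right	supratentorial	0
T_PREF_left	left	supratentorial	0
T_PREF_right	right	supratentorial	0
T_PREM_left	left	supratentorial	0
T_PREM_right	right	supratentorial	0
T_PREC_left	left	supratentorial	0
T_PREC_right	right	supratentorial	0
T_POSTC_left	left	supratentorial	0
T_POSTC_right	right	supratentorial	0
T_PAR_left	left	supratentorial	0
T_PAR_right	right	supratentorial	0
T_OCC_left	left	supratentorial	0
T_OCC_right	right	supratentorial	0
ST_FO_left	left	supratentorial	1
ST_FO_right	right	supratentorial	1
ST_PREF_left	left	supratentorial	1
ST_PREF_right	right	supratentorial	1
ST_PREM_left	left	supratentorial	1
ST_PREM_right	right	supratentorial	1
ST_PREC_left	left	supratentorial	1
ST_PREC_right	right	supratentorial	1
ST_POSTC_left	left	supratentorial	1
ST_POSTC_right	right	supratentorial	1
ST_PAR_left	left	supratentorial	1
ST_PAR_right	right	supratentorial	1
ST_OCC_left	left	supratentorial	1
ST_OCC_right	right	supratentorial	1
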