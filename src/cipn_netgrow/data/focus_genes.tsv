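agent_group	gene
P	ABCC1
P	ABCC2
P	ABCG2
P	ACYP2
P	AGXT
P	BTG4
P	CAMK2N1
P	CCNH
P	DLEU7
P	ERCC1
P	FARS2
P	FOXC1
P	GMDS
P	GSTM1
P	GSTM3
P	GSTP1
P	ITGA1
P	ITGB3
P	KCNN3
P	LYRM4
P	PELO
P	POU2AF1
P	SCN10A
P	SCN4A
P	TAC1
P	TSPYL6
T	ABCB1
T	ABCC2
T	ABCG1
T	CYP1B1
T	CYP2C8
T	CYP3A4
T	CYP3A5
T	EPHA4
T	EPHA5
T	EPHA6
T	FANCD2
T	FGD4
T	FZD3
T	GSTP1
T	LIMK2
T	SLCO1B1
T	SPIDR
T	TUBB2A
T	XKR4
P/T	ABCA1
P/T	BCL2
P/T	CYP2C8
P/T	ERCC1
P/T	OPRM1
P/T	SOX10
P/T	TRPV1
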