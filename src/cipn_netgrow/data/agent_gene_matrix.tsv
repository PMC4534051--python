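gene	P	T	P/T	B	B/V	Th	M	Cyt	P/F	P/S	T/G	P/F/L	P/F/I	Pr/V/M	P/C	P/F/I/L	R/Cyc/D/V/Pr
GSTP1	7	1	0	0	0	0	0	0	1	1	0	1	1	0	0	0	0
ERCC1	2	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
ACYP2	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
FARS2	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
GSTM1	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
TAC1	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
ABCC2	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
ABCC1	1	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
ABCG2	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
AGXT	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
BTG4	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CAMK2N1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CCNH	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
DLEU7	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
FOXC1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
GMDS	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
GSTM3	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
ITGA1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
ITGB3	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
KCNN3	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
LYRM4	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
PELO	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
POU2AF1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
SCN10A	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
SCN4A	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
TSPYL6	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CYP2C8	0	4	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
ABCB1	0	3	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
EPHA5	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
EPHA6	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
TUBB2A	0	2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CYP3A4	0	1	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0
CYP3A5	0	1	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0
ABCG1	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CYP1B1	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
EPHA4	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
FANCD2	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
FGD4	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
FZD3	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
LIMK2	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
SLCO1B1	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
SPIDR	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
XKR4	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
ABCA1	0	0	1	0	0	1	0	0	0	0	0	0	0	0	0	0	0
BCL2	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
OPRM1	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
SOX10	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
TRPV1	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
CTLA4	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
CTSS	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
CYP17A1	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
DYNC1I1	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
GJC3	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
PSMB1	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
TCF4	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0
PPARD	0	0	0	0	1	1	0	0	0	0	0	0	0	0	0	0	0
ALOX12	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
AURKA	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
CASP9	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
CPT1C	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
DPYD	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
ERCC3	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
ERCC4	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
GLI1	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
IGF1R	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
MBL2	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
MKI67	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
MYO5A	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
RHOBTB2	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
SOD2	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
SOX8	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0
GSTT1	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0
ICAM1	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0
SERPINB2	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0
SLC12A6	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0
ASTN2	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0
IYD	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0
PXDC1	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0
NME1	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0
RRM1	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0
XRCC1	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0
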