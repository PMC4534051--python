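year	first_author	ethnicity	cancer_type	sample_size	phenotype	significant_genes	agent_group
2003	Aplenc R	W,AA,H	Acute lymphoblastic leukemia	533	Peripheral neuropathy	CYP3A4,CYP3A5	Pr/V/M
2004	Isla D	W	Lung	62	Docetaxel-cisplatin-treated neurological	None	P/T
2006	Lecomte T	W	Gastrointestinal solid tumors	64	Oxaliplatin-related cumulative neuropathy	GSTP1	P
2006	Sissung TM	W	N/A	26	Paclitaxel-induced neuropathy	ABCB1	T
2007	Gamelin L	W	Colon, rectum	145	Oxaliplatin-induced neurotoxicity	AGXT	P
2007	Marsh S	NA	Ovarian	914	Paclitaxel/docetaxel-induced neuropathy	None	T
2007	Oldenburg J	W	Testicular	238	Self-reported chemotherapy-induced long-term toxicities	GSTP1	P
2007	Ruzzo A	W	Colorectal	166	Oxaliplatin-induced neurotoxicity	GSTP1	P
2008	Keam B	A	Gastric	73	Peripheral sensory neuropathy	None	P/C
2008	Pare L	W	Colorectal	126	Cumulative oxaliplatin-induced neuropathy	None	P
2008	Sissung TM	NA	Prostate	73	Docetaxel-induced neuropathy	ABCB1	T
2009	Argyriou AA	W	Colorectal	62	Oxaliplatin-induced peripheral neuropathy	None	P
2009	Goekkurt E	W	Gastric	134	Neurotoxicity	GSTP1	P/F
2009	Green H	W	Ovarian	38	Sensory/motor neuropathy	None	T
2009	Kim HS	A	Epithelial ovarian	118	Taxane/platinum-induced neurotoxicity	ERCC1	P/T
2009	Kweekel DM	W	Colorectal	91	Neurotoxicity	None	P/F/I
2009	Mir O	W	Breast, lung, prostate	58	Docetaxel(Taxotere)-induced peripheral neuropathy	GSTP1	T
2009	Seo BG	A	Gastric	94	Neuropathy	None	P/F
2010	Antonacopoulou AG	W	Colorectal	55	Chronic oxaliplatin-induced peripheral neuropathy	ITGB3	P
2010	Boige V	W	Colorectal	349	FOLFOX-induced severe neurologic toxicity	None	P/F/I/L
2010	Chen YC	A	Colorectal	166	Oxaliplatin-induced chronic cumulative neuropathy	GSTP1	P
2010	Cho HJ	A	Diffuse large B-cell lymphoma	94	Chemotherapy-related neurotoxicity	None	R/Cyc/D/V/Pr
2010	Inada M	A	Colorectal	51	Oxaliplatin-induced peripheral neuropathy	ERCC1,GSTP1	P
2010	Kanai M	A	Colorectal	82	Early-onset oxaliplatin-induced neuropathy	None	P
2010	Khrunin AV	W	Ovarian	104	Cisplatin-based neuropathy	GSTM1,GSTM3	P
2010	Li QF	A	Gastric	92	Neurological toxicity	GSTP1	P/S
2010	McLeod HL	W,A,AA,H	Metastatic colorectal	520	Diarrhea, vomiting, paresthesia, febrile neutropenia and neutropenia	GSTP1	P/F/I
2010	Ofverholm A	W	Breast, ovarian	36	Occurrence and degree of neurotoxicity	None	T
2010	Rizzo R	W	Breast	95	Taxane-induced hypersensitivity and sensory neuropathy	None	T
2011	Basso M	W	Colorectal, pancreatic, bile ducts	40	Acute oxaliplatin neurotoxicity	KCNN3	P
2011	Bergmann TK	W	Ovarian	119	Sensory neuropathy	None	T
2011	Bergmann TK	W	Ovarian	92	Sensory neuropathy	None	T
2011	Broyl A	W	Multiple myeloma	369	Bortezomib/vincristine-induced peripheral neuropathy	RHOBTB2,CPT1C,SOX8,CASP9,ALOX12,IGF1R,SOD2,MYO5A,MBL2,PPARD,ERCC4,ERCC3,AURKA,MKI67,GLI1,DPYD,ABCC1	B/V
2011	Cibeira MT	W	Multiple myeloma	28	Thalidomide-induced peripheral neuropathy	GSTT1	Th
2011	Corthals SL	W	Multiple myeloma	238	Bortezomib induced peripheral neuropathy	CYP17A1	B
2011	Favis R	W	Myeloma	139	Bortezomib-induced peripheral neuropathy	CTLA4,PSMB1,CTSS,GJC3,DYNC1I1,TCF4	B
2011	Hong J	A	Colorectal	52	Sensory neuropathy	GSTP1	P/F/L
2011	Johnson DC	W	Multiple myeloma	1495	Thalidomide-related peripheral neuropathy	ABCA1,ICAM1,PPARD,SERPINB2,SLC12A6	Th
2011	Leskela S	W	Lung, breast, ovary, uterus, head and neck	118	Neurotoxicity	CYP2C8,CYP3A5	T
2011	Sucheston LE	W,AA	Breast	888	Taxane-induced neurotoxicity	FANCD2	T
2012	Baldwin RM	W,AA,A	Breast	855	Paclitaxel induced peripheral sensory neuropathy	FGD4,FZD3,EPHA5	T
2012	Braunagel D	W	Acute myeloid leukemia	360	Cytarabine-induced neurotoxicity	NME1	Cyt
2012	Fung C	W,A,AA,H	Testicular germ cell tumor	137	Cisplatin-induced neurotoxicity, peripheral neuropathy	None	P
2012	Hasmats J	W	Ovarian, lung, carcinoma in uteri/peritoneal/breast	94	Paclitaxel/carboplatin-induced neuropathy	ABCA1	P/T
2012	Hertz DL	W,AA	Breast	111	Peripheral neuropathy	CYP2C8	P/T
2012	Leandro-Garcia LJ	W	Ovary, lung, breast	214	Paclitaxel-induced peripheral neuropathy	TUBB2A	T
2012	Won HH	A	Colon	96	Severe oxaliplatin-induced chronic peripheral neuropathy	TAC1,FOXC1,GMDS,ITGA1,PELO,ACYP2,TSPYL6,DLEU7,BTG4,POU2AF1,CAMK2N1,FARS2,LYRM4	P
2013	Argyriou AA	W	Colorectal	200	Oxaliplatin-induced peripheral neuropathy	SCN4A,SCN10A	P
2013	Bergmann TK	W	Ovarian	241	Paclitaxel induced neuropathy	None	T
2013	Cecchin E	W	Colorectal	144	Oxaliplatin neurotoxicity	ABCC1,ABCC2	P
2013	de Graan AJ	W	Esophagus, ovary, cervix, endometrial, breast, lung, head/neck	261	Paclitaxel-induced neurotoxicity	CYP3A4	T
2013	Hertz DL	W,AA	Breast	209	Paclitaxel-induced neuropathy	CYP2C8	T
2013	Kumamoto K	A	Colorectal	63	Oxaliplatin-induced sensory peripheral neuropathy	GSTP1,GSTM1	P
2013	Leandro-Garcia LJ	W	Ovary, fallopian tube, peritoneum, lung, uterus, breast	144	Paclitaxel induced peripheral sensory neuropathy	EPHA4,EPHA6,EPHA5,XKR4,LIMK2	T
2013	Lee KH	A	Colon	292	Sensory neuropathy	XRCC1	P/F/L
2013	Liu YP	A	Gastric	126	Oxaliplatin-induced neurotoxicity	GSTP1	P
2013	McWhinney-Glass S	NA	Ovarian	404	Platinum/taxane-induced neurotoxicity	SOX10,BCL2,OPRM1,TRPV1	P/T
2013	Oguri T	A	Colorectal	70	Oxaliplatin-induced chronic peripheral neurotoxicity	ACYP2,FARS2,ERCC1,TAC1	P
2014	Abraham JE	W	Breast	1303	Taxane-related sensory neuropathy	ABCB1,TUBB2A,CYP2C8,ABCC2,CYP1B1,SPIDR,SLCO1B1,EPHA6	T
2014	Bhojwani D	NA	Acute lymphoblastic leukemia	369	Methotrexate-induced neurotoxicity	ASTN2,PXDC1,IYD	M
2014	Custodio A	W	Colon	206	Oxaliplatin-induced peripheral neuropathy	CCNH,ABCG2	P
2014	Hertz DL	W,AA,A	Breast	412	Paclitaxel-induced peripheral neuropathy	CYP2C8,ABCG1	T
2014	Khrunin AV	W	Ovarian	104	Cisplatin-based neurotoxicity	None	P
2014	Lee SY	A	Breast	85	Paclitaxel and gemcitabine combination chemotherapy neurotoxicity	RRM1	T/G
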