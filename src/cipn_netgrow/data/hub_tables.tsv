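analysis	symbol	connections	is_focus
platinum	IL6	70	0
platinum	TNF	69	0
platinum	CXCL8	56	0
platinum	IL1B	55	0
platinum	ERK1/2	54	0
platinum	VEGFA	52	0
platinum	MAPK1	51	0
platinum	NFkB (complex)	46	0
platinum	P38 MAPK	45	0
platinum	TGFB1	43	0
platinum	COL18A1	42	0
platinum	CCL2	39	0
platinum	IFNG	38	0
platinum	PTGS2	37	0
platinum	ERK	34	0
platinum	TP53	34	0
platinum	MAPK3	33	0
platinum	Akt	32	0
platinum	STAT3	30	0
platinum	CD3	29	0
platinum	JUN	29	0
platinum	PI3K (complex)	29	0
platinum	EGFR	28	0
platinum	MMP1	28	0
platinum	HGF	27	0
platinum	Jnk	27	0
platinum	CCL5	26	0
platinum	CD40	26	0
platinum	IL1A	26	0
platinum	ITGB1	26	0
platinum	MMP2	25	0
platinum	Cg	24	0
platinum	FN1	24	0
platinum	RELA	24	0
platinum	TLR4	23	0
platinum	Vegf	23	0
platinum	CXCL10	22	0
platinum	EGF	21	0
platinum	ITGB3	21	1
platinum	MAPK14	21	0
platinum	NFKBIA	21	0
platinum	SP1	21	0
platinum	STAT1	21	0
platinum	AKT1	20	0
platinum	HIF1A	20	0
platinum	SRC	20	0
platinum	TERT	20	0
platinum	Pkc(s)	19	0
platinum	CTNNB1	18	0
platinum	Focal adhesion kinase	18	0
platinum	FOS	18	0
platinum	HDAC1	18	0
platinum	IgG	18	0
platinum	ITGAV	18	0
platinum	NFKB1	18	0
platinum	CD44	17	0
platinum	FGF2	17	0
platinum	Lh	17	0
platinum	MAPK8	17	0
platinum	SYK	17	0
platinum	Ap1	16	0
platinum	CCND1	16	0
platinum	IGF1	16	0
platinum	PRKCD	16	0
platinum	TREM1	16	0
platinum	OSM	15	0
platinum/taxane	TP53	42	0
platinum/taxane	BCL2	28	1
platinum/taxane	MYC	16	0
platinum/taxane	PARP1	16	0
platinum/taxane	P38 MAPK	15	0
platinum/taxane	TNF	15	0
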