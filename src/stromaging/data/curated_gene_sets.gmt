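senescence	cellular senescence effectors [refs 17-19,69-71]	CDKN1A	CDKN2A	TP53	RB1	GLB1
ddr	DNA damage response axis [refs 21,73]	ATM	NBN	CHEK2
sasp	senescence-associated secretory profile [refs 17,21,22,26]	IL1A	IL6	IL6R	IL6ST	IL8	CXCL1	CXCL2	CXCL3	CSF2	IL7	ICAM1	TNFRSF11B	HGF	IGFBP4	CCL8	PLAUR	IGFBP2	CCL26	IL13	CCL20	ICAM3	PGF	TNFRSF1A	TNFRSF1B	CCL13	CCL16	TNFRSF10C	CCL2	FAS	ANG	IGFBP6	IL1B	(CCL3)	TIMP2	IL11	OSM	LEP	AXL	KITLG	FGF7	IL15	FGF2	IGFBP1	MIF
ast	autophagy-to-senescence transition, reverse Warburg effect [refs 33-37]	CAV1	CTSB	BNIP3	PRKAA1	PRKAA2	LAMP2	MAP1LC3B	ATG16L1	HIF1A	NFKB1	DRAM1	TP73	MAPK8	E2F1	STK11
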