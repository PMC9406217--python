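G2M	synthetic example snapshot: mitotic G2-G2/M phases	CDK1	CCNB1	CCNB2	PLK1	FOXM1	AURKA	AURKB	CDC25C	WEE1	BUB1	CDC20	CHEK1
kinome	synthetic example snapshot: human kinome	CDK1	PLK1	AURKA	AURKB	WEE1	BUB1	CHEK1	EGFR	SRC	ABL1	MAPK1	AKT1
matrisome	synthetic example snapshot: matrisome	FN1	COL1A1	COL6A1	TNC	LTBP1	LAMA1	MMP13	SPARC	THBS1	ANGPTL4
adhesion	synthetic example snapshot: cell adhesion	ITGB1	ITGA5	CDH1	CDH2	CXADR	NCAM1	ICAM1	VCAM1	TNC	FN1
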