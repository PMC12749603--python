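TP53	editable pathway membership	TP53	MDM2	MDM4	ATM	CHEK2	RPS6KA3	CDKN2A	TP53BP1
WNT	editable pathway membership	CTNNB1	APC	AXIN1	AXIN2	TCF7L2	WIF1	RNF43	ZNRF3	DKK1	LRP5	LRP6	FZD1	WNT1
PI3K	editable pathway membership	PIK3CA	PIK3R1	PTEN	AKT1	AKT2	MTOR	TSC1	TSC2	RICTOR	RPTOR	STK11	INPP4B
NOTCH	editable pathway membership	NOTCH1	NOTCH2	NOTCH3	NOTCH4	FBXW7	CREBBP	EP300	SPEN
RTK_RAS	editable pathway membership	KRAS	HRAS	NRAS	BRAF	RAF1	EGFR	ERBB2	ERBB3	ERBB4	MAP2K1	MAP3K1	NF1	PTPN11	SOS1
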