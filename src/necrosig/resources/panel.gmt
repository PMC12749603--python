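STATHMIN_UP	editable placeholder gene list; replace with your curated set	STMN1	TPX2	AURKA	BUB1	CCNB1
PCNA_UP	proliferation meta-set placeholder	PCNA	MKI67	MCM2	MCM3	MCM4	MCM5	MCM6	MCM7	TOP2A	RRM2
HYPOXIA_UP	hypoxia response placeholder	HIF1A	VEGFA	SLC2A1	CA9	LDHA	PGK1	ADM	NDRG1
NESTIN_UP	single-gene stemness marker	NES
EMT_UP	epithelial-mesenchymal transition placeholder	VIM	ZEB1	ZEB2	SNAI1	SNAI2	TWIST1	FN1
EMT_DN	epithelial-mesenchymal transition placeholder	CDH1	CLDN3	CLDN4	CLDN7
LUMINAL_PROGENITOR_UP	luminal progenitor placeholder	KIT	ELF5	CD14	ALDH1A3
MATURE_LUMINAL_UP	mature luminal placeholder	ESR1	FOXA1	GATA3	AR
MAMMARY_STEM_CELL_UP	mammary stem cell placeholder	ITGB1	ITGA6	KRT5	KRT14	TP63
ONCOTYPE_PROLIF_UP	proliferation axis of the 21-gene assay, unweighted placeholder	MKI67	AURKA	BIRC5	CCNB1	MYBL2
ONCOTYPE_ESTROGEN_DN	estrogen axis of the 21-gene assay, unweighted placeholder	ESR1	PGR	BCL2	SCUBE2
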