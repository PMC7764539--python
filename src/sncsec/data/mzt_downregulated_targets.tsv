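target_set	contrast	symbol
hsa-let-7b-5p	down_D3_vs_D2	AGPAT3
hsa-let-7b-5p	down_D3_vs_D2	AKT2
hsa-let-7b-5p	down_D3_vs_D2	GAB2
hsa-let-7b-5p	down_D3_vs_D2	GABBR2
hsa-let-7b-5p	down_D3_vs_D2	LRRC17
hsa-let-7b-5p	down_D3_vs_D2	MID1
hsa-let-7b-5p	down_D3_vs_D2	RTTN
hsa-let-7b-5p	down_D3_vs_D2	SPATA6
hsa-let-7b-5p	down_D3_vs_D2	TAF9B
hsa-let-7b-5p	down_D3_vs_D2	TCEB3B
hsa-let-7b-5p	down_D3_vs_D2	WDR37
hsa-let-7b-5p	down_D3_vs_D2	XYLT1
hsa-let-7i-5p	down_D3_vs_D2	AKT2
hsa-let-7i-5p	down_D3_vs_D2	BUB1B
hsa-let-7i-5p	down_D3_vs_D2	DAAM1
hsa-let-7i-5p	down_D3_vs_D2	TRAFD1
hsa-let-7i-5p	down_D3_vs_D2	WDR37
hsa-let-7i-5p	down_D3_vs_D2	XYLT1
piRNA_pool	down_D3_vs_D2	CSGALNACT1
piRNA_pool	down_D3_vs_D2	EHMT1
piRNA_pool	down_D3_vs_D2	KIFC3
piRNA_pool	down_D3_vs_D2	LYPD6
piRNA_pool	down_D3_vs_D2	MEX3D
piRNA_pool	down_D3_vs_D2	TPD52
piRNA_pool	down_D3_vs_D2	ZBTB38
hsa-let-7b-5p	down_D3_vs_D5	ACSL6
hsa-let-7b-5p	down_D3_vs_D5	AKT2
hsa-let-7b-5p	down_D3_vs_D5	ARHGAP28
hsa-let-7b-5p	down_D3_vs_D5	ATP2B1
hsa-let-7b-5p	down_D3_vs_D5	ATPAF1
hsa-let-7b-5p	down_D3_vs_D5	B3GNT5
hsa-let-7b-5p	down_D3_vs_D5	CCR7
hsa-let-7b-5p	down_D3_vs_D5	FRAS1
hsa-let-7b-5p	down_D3_vs_D5	GAB2
hsa-let-7b-5p	down_D3_vs_D5	IGF2BP2
hsa-let-7b-5p	down_D3_vs_D5	IL11RA
hsa-let-7b-5p	down_D3_vs_D5	KIAA0319L
hsa-let-7b-5p	down_D3_vs_D5	MID1
hsa-let-7b-5p	down_D3_vs_D5	MLLT4
hsa-let-7b-5p	down_D3_vs_D5	PAPOLG
hsa-let-7b-5p	down_D3_vs_D5	PCSK6
hsa-let-7b-5p	down_D3_vs_D5	PDXK
hsa-let-7b-5p	down_D3_vs_D5	PFAS
hsa-let-7b-5p	down_D3_vs_D5	PLCXD1
hsa-let-7b-5p	down_D3_vs_D5	PLSCR3
hsa-let-7b-5p	down_D3_vs_D5	REEP3
hsa-let-7b-5p	down_D3_vs_D5	RGS16
hsa-let-7b-5p	down_D3_vs_D5	VPS33A
hsa-let-7b-5p	down_D3_vs_D5	ZNRF1
hsa-let-7i-5p	down_D3_vs_D5	AKT2
hsa-let-7i-5p	down_D3_vs_D5	ARHGAP28
hsa-let-7i-5p	down_D3_vs_D5	ATP2B1
hsa-let-7i-5p	down_D3_vs_D5	DEPDC1
hsa-let-7i-5p	down_D3_vs_D5	DPH1
hsa-let-7i-5p	down_D3_vs_D5	ELMOD2
hsa-let-7i-5p	down_D3_vs_D5	FBXO22
hsa-let-7i-5p	down_D3_vs_D5	FRAS1
hsa-let-7i-5p	down_D3_vs_D5	FZD5
hsa-let-7i-5p	down_D3_vs_D5	GPR56
hsa-let-7i-5p	down_D3_vs_D5	IGSF3
hsa-let-7i-5p	down_D3_vs_D5	MGLL
hsa-let-7i-5p	down_D3_vs_D5	MTAP
hsa-let-7i-5p	down_D3_vs_D5	NAGA
hsa-let-7i-5p	down_D3_vs_D5	PHF16
hsa-let-7i-5p	down_D3_vs_D5	PLCXD1
hsa-let-7i-5p	down_D3_vs_D5	QARS
hsa-let-7i-5p	down_D3_vs_D5	RBPMS
hsa-let-7i-5p	down_D3_vs_D5	TEAD1
hsa-let-7i-5p	down_D3_vs_D5	VPS33A
piRNA_pool	down_D3_vs_D5	B3GALT6
piRNA_pool	down_D3_vs_D5	CNDP2
piRNA_pool	down_D3_vs_D5	COL4A1
piRNA_pool	down_D3_vs_D5	DLX4
piRNA_pool	down_D3_vs_D5	EHD4
piRNA_pool	down_D3_vs_D5	EXT2
piRNA_pool	down_D3_vs_D5	FOXRED1
piRNA_pool	down_D3_vs_D5	HEMK1
piRNA_pool	down_D3_vs_D5	JUP
piRNA_pool	down_D3_vs_D5	MX1
piRNA_pool	down_D3_vs_D5	RGS3
piRNA_pool	down_D3_vs_D5	SLC45A4
piRNA_pool	down_D3_vs_D5	SOD2
piRNA_pool	down_D3_vs_D5	SP3
piRNA_pool	down_D3_vs_D5	STX3
piRNA_pool	down_D3_vs_D5	TEAD3
piRNA_pool	down_D3_vs_D5	TRERF1
piRNA_pool	down_D3_vs_D5	VPS13A
piRNA_pool	down_D3_vs_D5	ZBTB38
hsa-let-7b-5p	down_D5_vs_D3	AGPAT3
hsa-let-7b-5p	down_D5_vs_D3	ATPAF1
hsa-let-7b-5p	down_D5_vs_D3	GNAL
hsa-let-7b-5p	down_D5_vs_D3	HOXA1
hsa-let-7b-5p	down_D5_vs_D3	LRRC17
hsa-let-7b-5p	down_D5_vs_D3	NEDD4L
hsa-let-7b-5p	down_D5_vs_D3	PAPOLG
hsa-let-7b-5p	down_D5_vs_D3	TMEM2
hsa-let-7b-5p	down_D5_vs_D3	WDR37
hsa-let-7b-5p	down_D5_vs_D3	XYLT1
hsa-let-7b-5p	down_D5_vs_D3	ZNF280B
hsa-let-7b-5p	down_D5_vs_D3	ZNF324
hsa-let-7b-5p	down_D5_vs_D3	ZNF557
hsa-let-7b-5p	down_D5_vs_D3	ZNF814
hsa-let-7i-5p	down_D5_vs_D3	ARG2
hsa-let-7i-5p	down_D5_vs_D3	CDC14B
hsa-let-7i-5p	down_D5_vs_D3	CPD
hsa-let-7i-5p	down_D5_vs_D3	DAAM1
hsa-let-7i-5p	down_D5_vs_D3	HOXA1
hsa-let-7i-5p	down_D5_vs_D3	NRAS
hsa-let-7i-5p	down_D5_vs_D3	PAFAH1B2
hsa-let-7i-5p	down_D5_vs_D3	PSD3
hsa-let-7i-5p	down_D5_vs_D3	TMEM2
hsa-let-7i-5p	down_D5_vs_D3	TRAFD1
hsa-let-7i-5p	down_D5_vs_D3	WDR37
hsa-let-7i-5p	down_D5_vs_D3	XYLT1
hsa-let-7i-5p	down_D5_vs_D3	ZNF280B
hsa-let-7i-5p	down_D5_vs_D3	ZNF557
hsa-let-7i-5p	down_D5_vs_D3	ZNF814
piRNA_pool	down_D5_vs_D3	AKAP1
piRNA_pool	down_D5_vs_D3	API5
piRNA_pool	down_D5_vs_D3	BTRC
piRNA_pool	down_D5_vs_D3	ELF1
piRNA_pool	down_D5_vs_D3	G3BP2
piRNA_pool	down_D5_vs_D3	GBX2
piRNA_pool	down_D5_vs_D3	GON4L
piRNA_pool	down_D5_vs_D3	HOXB6
piRNA_pool	down_D5_vs_D3	KIFC3
piRNA_pool	down_D5_vs_D3	MGAT5B
piRNA_pool	down_D5_vs_D3	MVP
piRNA_pool	down_D5_vs_D3	NPHP4
piRNA_pool	down_D5_vs_D3	PAX8
piRNA_pool	down_D5_vs_D3	PRAME
piRNA_pool	down_D5_vs_D3	SP1
piRNA_pool	down_D5_vs_D3	STX3
piRNA_pool	down_D5_vs_D3	SYN2
piRNA_pool	down_D5_vs_D3	TPD52
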