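time_point	gene
29 days	CSRP1
15 days	ABHD3
8 days	CROT
4 days	C1R
1 day	A1BG
9 h	ABHD3
6 h	CSF1R
3 h	CYP26B1
29 days	DUSP6
15 days	CSRP1
8 days	HSD11B2
4 days	DUSP6
1 day	CYP26B1
9 h	BHLHE40
6 h	CYP26B1
3 h	NR1D1
29 days	EGR1
15 days	CYP27A1
8 days	LPL
4 days	HBB
1 day	CYP27A1
9 h	CEBPB
6 h	GPNMB
3 h	NR1D2
29 days	HBB
15 days	EBP
8 days	PTPRF
4 days	EGR1
1 day	CYP26B1
9 h	SLC16A10
6 h	LPL
3 h	GPNMB
29 days	GPNMB
15 days	DUSP6
8 days	PHGDH
4 days	HBB
1 day	KCNJ8
9 h	PPP2R1B
6 h	LPL
3 h	S100A9
29 days	NCALD
15 days	LAMC2
8 days	PPP2R1B
4 days	LPL
1 day	S100A9
9 h	MGAT2
6 h	NARS
3 h	NR3C1
29 days	NT5E
15 days	PHLDA1
8 days	POLR3G
4 days	SLC1A4
1 day	TARS
9 h	WARS
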