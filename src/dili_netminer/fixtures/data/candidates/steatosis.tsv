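time_point	gene
29 days	CROT
15 days	CROT
8 days	A1BG
4 days	ME1
1 day	ACLY
9 h	ACLY
6 h	ACLY
3 h	INSIG1
29 days	ME1
15 days	ME1
8 days	CROT
4 days	SLC22A8
1 day	CCL2
9 h	EGR1
6 h	SGK1
3 h	S100A9
29 days	EGR1
15 days	CROT
8 days	ME1
4 days	ME1
1 day	EGR1
9 h	PHGDH
6 h	SLC22A8
3 h	ICAM1
29 days	SREBF1
15 days	KLKB1
8 days	LAMC2
4 days	ME1
1 day	MYC
9 h	S100A9
6 h	SOD2
3 h	SREBF1
29 days	TARS
15 days	USP18
8 days	XBP1
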