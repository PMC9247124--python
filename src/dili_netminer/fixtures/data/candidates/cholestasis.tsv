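time_point	gene
29 days	ABCC2
15 days	ABCC2
8 days	CD63
4 days	A1BG
1 day	ABHD3
9 h	A1BG
6 h	CARS
3 h	A1BG
29 days	ADSSL1
15 days	ACLY
8 days	CYP26B1
4 days	ABHD3
1 day	CYP26B1
9 h	ABHD3
6 h	EGR1
3 h	ABHD3
29 days	BHLHE40
15 days	AGT
8 days	CYP7A1
4 days	ACLY
1 day	EGR1
9 h	BHLHE40
6 h	HSPB8
3 h	IFIT1
29 days	CD63
15 days	CSRP1
8 days	BHLHE40
4 days	MID1IP1
1 day	CEBPB
9 h	NARS
6 h	NQO1
3 h	CFD
29 days	CYP27A1
15 days	C1R
8 days	UHRF1
4 days	CREM
1 day	S100A9
9 h	USP18
6 h	CREM
3 h	IFIT1
29 days	MID1IP1
15 days	CYP7A1
8 days	CSRP1
4 days	IL13RA1
1 day	TM7SF2
9 h	MID1IP1
6 h	CYP7A1
3 h	S100A9
29 days	NQO1
15 days	IP6K2
8 days	SREBF1
4 days	MID1IP1
1 day	NQO1
9 h	PPP2R1B
6 h	S100A9
3 h	SLC16A10
29 days	SREBF1
15 days	USP18
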