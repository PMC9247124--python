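time_point	gene
29 days	HBB
15 days	HBB
8 days	SLPI
4 days	SLPI
1 day	EGR1
9 h	EGR1
6 h	EGR1
29 days	CROT
15 days	SLPI
8 days	CROT
4 days	CROT
1 day	HMOX1
9 h	HMOX1
6 h	MID1IP1
29 days	FOXA2
15 days	EGR1
8 days	SLC6A6
4 days	CSRP1
1 day	MID1IP1
9 h	XBP1
6 h	RAB30
29 days	SLC6A6
15 days	CROT
8 days	RAB30
4 days	ABHD3
1 day	TSR1
9 h	MID1IP1
6 h	CEBPB
29 days	CSRP1
15 days	SLC6A6
8 days	TM7SF2
4 days	IP6K2
1 day	AURKA
9 h	RAB30
6 h	CROT
29 days	REEP5
15 days	CSRP1
8 days	SREBF1
4 days	RAB30
1 day	CYP26B1
9 h	RAB30
6 h	PPP2R1B
29 days	CYP26B1
15 days	SREBF1
8 days	APOM
4 days	RAB30
1 day	DNAJB9
9 h	SREBF1
6 h	CEBPB
29 days	EBNA1BP2
15 days	WDR77
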