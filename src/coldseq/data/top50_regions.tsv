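region	gene_id	symbol	logfc_0C	logfc_4C	logfc_10C
0C&4C&10C	At3g50380	AT3G50380	13.1	12.6	10.2
0C&4C&10C	At2g36850	GSL8	12.8	12.2	8.1
0C&4C&10C	At3g63460	SEC31B	12.7	13.0	11.4
0C&4C&10C	At4g00710	BSK3	12.7	12.1	8.3
0C&4C&10C	At1g21380	TOL3	12.6	12.9	10.8
0C&4C&10C	At5g17030	UGT78D3	12.5	12.6	8.3
0C&4C&10C	At2g02570	SPF30	12.4	11.8	9.7
0C&4C&10C	At3g54500	LNK2	12.2	12.3	8.4
0C&4C&10C	At5g47430	AT5G47430	12.1	11.5	10.8
0C&4C&10C	At3g55610	P5CS2	11.9	11.7	8.5
0C&4C&10C	At4g16990	RLM3	11.9	11.8	10.8
0C&4C&10C	At1g01060	LHY	11.8	12.5	9.1
0C&4C&10C	At5g62570	CBP60A	11.7	11.0	9.8
0C&4C&10C	At4g25450	ABCB28	11.6	11.4	11.2
0C&4C&10C	At2g42540	COR15A	11.6	11.7	9.0
0C&4C&10C	At5g37130	AT5G37130	11.6	11.2	6.7
0C&4C&10C	At4g36980	AT4G36980	11.5	10.9	5.4
0C&4C&10C	At2g23420	NAPRT2	11.1	12.2	8.5
0C&4C&10C	At3g57660	NRPA1	11.1	10.5	10.6
0C&4C&10C	At3g17609	HYH	10.7	13.0	10.7
0C&4C&10C	At1g80270	PPR596	10.7	11.4	10.6
0C&4C&10C	At5g20830	SUS1	10.6	12.0	8.8
0C&4C&10C	At3g25840	PRP4KA	10.2	9.5	8.9
0C&4C&10C	At1g11720	SS3	10.0	9.9	10.7
0C&4C&10C	At1g05200	GLR3.4	9.5	11.0	11.4
0C&4C&10C	At4g01985	AT4G01985	9.5	9.2	6.7
0C&4C&10C	At5g37260	CIR1	9.3	7.6	5.8
0C&4C&10C	At1g48540	AT1G48540	9.1	9.3	8.2
0C&4C&10C	At1g03080	NET1D	8.6	8.7	7.7
0C&4C&10C	At4g31210	AT4G31210	8.3	9.8	10.1
0C&4C&10C	At5g52310	LTI78	8.0	8.2	5.3
0C&4C	At2g24560	GGL15	10.2	10.4	
0C&4C	At5g61380	TOC1	9.5	7.9	
0C&4C	At1g72440	EDA25	9.2	8.3	
0C&4C	At1g09350	Gols3	9.0	8.9	
0C&4C	At3g20810	JMJD5	8.8	7.8	
0C&4C	At4g33980	COR28	8.7	7.9	
0C&4C	At4g18422	At4g18422	8.2	7.3	
0C&4C	At2g42520	RH37	7.7	7.4	
0C&4C	At1g70640	At1g70640	7.7	7.5	
4C&10C	At3g51240	F3H		10.1	7.5
4C&10C	At4g26530	FBA5		9.5	10.6
4C&10C	At5g38410	RBCS3B		8.5	8.3
4C&10C	At4g14690	ELIP2		7.9	7.4
4C&10C	At3g63340	AT3G63340		7.7	6.7
4C&10C	At5g35210	PTM		7.6	5.8
4C&10C	At5g27970	At5g27970		7.4	6.5
4C&10C	At4g04850	KEA3		7.4	5.9
0C&10C	At1g34260	FAB1D	8.5		5.6
0C&10C	At1g30620	MUR4	8.4		5.6
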