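position	ref	alt	rsid	gene	p	f_African	f_AfricanEuropean	f_CentralAsian	f_EastAsian	f_European	f_Hispanic	aa_change
chr9:98209594	G	A	rs357564	PTCH1	4.41E-10	0.23	0.26	0.45	0.64	0.37	0.43	P1164L
chr2:29416366	G	C	rs1881421	ALK	1.41E-22	0.65	0.55	0.48	0.77	0.36	0.62	D461E
chr2:29416481	T	C	rs1881420	ALK	9.99E-30	0.29	0.29	0.44	0.77	0.25	0.46	K423R
chrX:76937963	G	C	rs3088074	ATRX	2.03E-20	0.90	0.64	0.51	0.31	0.33	0.35	Q929E
chr10:88635779	C	A	rs11528010	BMPR1A	9.21E-40	0.77	0.63	0.24	0.69	0.24	0.39	P2T
chr17:41244936	G	A	rs799917	BRCA1	3.64E-25	0.88	0.62	0.49	0.43	0.32	0.34	P871L
chr15:40477831	G	A	rs1801376	BUB1B	1.65E-18	0.85	0.67	0.52	0.33	0.71	0.72	R212Q
chr17:37884037	C	G	rs61552325	ERBB2	6.41E-27	0.13	0.53	0.65	0.41	0.68	0.43	P1170A
chr16:89806347	A	T	rs7195906	FANCA	6.42E-40	0.73	0.65	0.66	0.98	0.38	0.64	I416N
chr16:89836323	C	T	rs7195066	FANCA	5.22E-48	0.63	0.59	0.65	0.98	0.32	0.62	G809D
chr16:89849480	C	T	rs2239359	FANCA	3.92E-23	0.72	0.63	0.51	0.80	0.38	0.59	G501S
chr16:89866043	T	C	rs7190823	FANCA	1.40E-36	0.66	0.58	0.65	0.98	0.39	0.65	T249A
chr13:28624294	G	A	rs1933437	FLT3	7.17E-11	0.30	0.41	0.68	0.73	0.61	0.54	T227M
chr2:47739551	A	G	rs2303424	MSH2	1.55E-15	0.62	0.60	0.43	0.73	0.36	0.45	Q915R
chr9:36840623	G	A	rs3780135	PAX5	2.03E-70	0.34	0.49	0.85	0.94	0.95	0.88	T293I
chr8:145737816	C	T	rs4251691	RECQL4	2.27E-13	0.13	0.23	0.63	0.48	0.44	0.49	R1005Q
chr3:47125385	G	A	rs4082155	SETD2	7.03E-09	0.23	0.41	0.63	0.59	0.53	0.42	P2029L
chr1:2488153	A	G	rs4870	TNFRSF14	2.53E-12	0.79	0.71	0.72	0.44	0.47	0.52	K17R
chr17:7579472	G	C	rs1042522	TP53	2.49E-18	0.37	0.52	0.41	0.56	0.74	0.69	P72R
chr14:81575005	C	A	rs3783941	TSHR	7.25E-07	0.62	0.64	0.73	0.39	0.65	0.59	R269S
chr8:30999280	G	T	rs1801195	WRN	0.001403	0.43	0.55	0.42	0.60	0.46	0.58	L541F
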