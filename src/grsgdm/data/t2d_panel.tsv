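rsid	proxy_rsid	chrom	pos	locus	effect_allele	other_allele	eaf	beta	source	proxy_effect_allele	proxy_other_allele	proxy_eaf
rs1493694		1	120526982	NOTCH2	T	C	0.11	0.110	Zeggini2008
rs340835		1	214163675	PROX1	A	G	0.49	0.062	Dupuis2010
rs780094		2	27741237	GCKR	C	T	0.62	0.011	Dupuis2010
rs7578597		2	43732823	THADA	T	C	0.89	0.141	Zeggini2008
rs243021		2	60584819	BCL11A	A	G	0.46	0.090	Voight2010
rs2943641	rs2943640	2	227093745	IRS1	C	T	0.65	0.083	Rung2009	C	A	0.65
rs1801282		3	12393125	PPARG	C	G	0.88	0.138	Altshuler2000
rs7612463		3	23336450	UBE2E2	C	A	0.89	0.102	Yamauchi2010
rs4607103	rs6795735	3	64711904	ADAMTS9	C	T	0.76	0.092	Zeggini2008	C	T	0.59
rs11708067	rs2877716	3	123065778	ADCY5	A	G	0.75	0.097	Dupuis2010	C	T	0.73
rs10010131		4	6292915	WFS1	G	A	0.60	0.104	Sandhu2007
rs4457053		5	76424949	ZBED3	G	A	0.32	0.150	Voight2010
rs7754840	rs9368222	6	20661250	CDKAL1	C	G	0.31	0.170	Zeggini2007	A	C	0.26
rs1635852		7	28189411	JAZF1	T	C	0.49	0.120	Zeggini2008
rs4607517	rs1799884	7	44235668	GCK	A	G	0.18	0.029	Dupuis2010	T	C	0.18
rs972283	rs4731702	7	130466854	KLF14	G	A	0.51	0.099	Kong2009	C	T	0.51
rs7845219		8	95937502	TP53INP1	T	C	0.50	0.093	Voight2010
rs13266634		8	118184783	SLC30A8	C	T	0.69	0.139	Sladek2007
rs10965250		9	22133284	CDKN2A/B	G	A	0.83	0.181	Zeggini2007
rs13292136		9	81952128	CHCHD9	C	T	0.93	0.182	Voight2010
rs12779790	rs11257655	10	12328010	CDC123/CAMK1D	G	A	0.18	0.088	Zeggini2008	T	C	0.21
rs5015480		10	94465559	HHEX/IDE	C	T	0.59	0.166	Zeggini2007
rs7903146		10	114758349	TCF7L2	T	C	0.29	0.335	Grant2006
rs2334499		11	1696849	HCCA2/DUSP8	T	C	0.42	0.080	Kong2009
rs231362		11	2691471	KCNQ1	G	A	0.52	0.104	Kong2009
rs163184		11	2847069	KCNQ1	G	T	0.48	0.083	Yasuda2008
rs5215		11	17408630	KCNJ11	C	T	0.36	0.089	Gloyn2003
rs1552224		11	72433098	CENTD2	A	C	0.84	0.123	Voight2010
rs1387153	rs10830963	11	92673828	MTNR1B	T	C	0.29	0.115	Prokopenko2009	G	C	0.28
rs2612067		12	66170163	HMGA2	G	T	0.10	0.180	Voight2010
rs1353362		12	71613276	TSPAN8/LGR5	C	T	0.28	0.103	Zeggini2008
rs7305618	rs12427353	12	121402932	HNF1A	C	T	0.77	0.112	Voight2010	G	C	0.81
rs1359790		13	80717156	SPRY2	G	A	0.71	0.096	Shu2010
rs7172432		15	62396389	C2CD4A/B	A	G	0.57	0.068	Yamauchi2010
rs7178572		15	77747190	HMG20A	G	A	0.71	0.068	Kooner2011
rs11634397		15	80432222	ZFAND6	G	A	0.66	0.102	Voight2010
rs4430796		17	36098040	HNF1B	G	A	0.48	0.130	Gudmundsson2007
rs2301142		X	152908152	DUSP9	A	G	0.85	0.086	Voight2010
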