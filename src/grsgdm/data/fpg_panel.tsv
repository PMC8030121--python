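rsid	proxy_rsid	chrom	pos	locus	effect_allele	other_allele	eaf	beta	source	proxy_effect_allele	proxy_other_allele	proxy_eaf
rs340874		1	214159256	PROX1	C	T	0.57	0.013	Dupuis2010
rs780094		2	27741237	GCKR	C	T	0.62	0.029	Dupuis2010
rs560887		2	169763148	G6PC2	C	T	0.70	0.075	Dupuis2010
rs11708067	rs2877716	3	123065778	ADCY5	A	G	0.75	0.027	Dupuis2010	C	T	0.73
rs11920090		3	170717521	SLC2A2	T	A	0.88	0.020	Dupuis2010
rs2191349		7	15064309	DGKB/TMEM195	T	G	0.55	0.030	Dupuis2010
rs4607517	rs1799884	7	44235668	GCK	A	G	0.18	0.062	Dupuis2010	T	C	0.18
rs13266634		8	118184783	SLC30A8	C	T	0.69	0.027	Dupuis2010
rs7034200		9	4289050	GLIS3	A	C	0.48	0.018	Dupuis2010
rs7903146		10	114758349	TCF7L2	T	C	0.29	0.023	Dupuis2010
rs11605924		11	45873091	CRY2	A	C	0.48	0.015	Dupuis2010
rs7944584		11	47336320	MADD	A	T	0.72	0.021	Dupuis2010
rs174550		11	61571478	FADS1	T	C	0.65	0.017	Dupuis2010
rs10830963		11	92708710	MTNR1B	G	C	0.28	0.067	Dupuis2010
rs11071657		15	62433962	C2CD4B	A	G	0.62	0.008	Dupuis2010
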