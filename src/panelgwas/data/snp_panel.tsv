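snp_id	gene	chromosome	position	allele_a1	allele_a2	is_tag	maf_hortega	maf_pizarra	callrate_hortega	callrate_pizarra
rs3101336	NEGR1	1	72523773	A	G	1	0.237	0.252	96.80	100
rs2568958	NEGR1	1	72537704	G	A	0	0.115	0.095	98.86	100
rs2815752	NEGR1	1	72585028	G	A	0	0.355	0.349	98.93	100
rs10913469	SEC16B	1	176180142	C	T	1	0.154	0.143	97.80	100
rs7566605	INSIG2	2	118552495	C	G	1	0.454	0.439	98.20	99.77
rs2867125	TMEM18	2	612827	C	T	0	0.351	0.397	97.47	100
rs6548238	TMEM18	2	624905	C	T	0	0.449	0.419	98.93	99.88
rs4854344	TMEM18	2	628144	G	T	1	0.380	0.387	98.73	99.88
rs17300539	ADIPOQ	3	188042154	A	G	1	0.433	0.403	98.53	99.54
rs3774261	ADIPOQ	3	188054253	A	G	1	0.496	0.484	98.20	99.54
rs7647305	ETV5	3	187316984	T	C	1	0.118	0.125	95	98.85
rs10938397	GNPDA2	4	44877284	G	A	1	0.195	0.198	97.80	100
rs12654778	ADRB2	5	148185934	A	G	1	0.363	0.330	98.13	100
rs4712652	PRL	6	22186594	T	C	1	0.346	0.375	97.07	97.58
rs10508503	PTER	10	16339957	T	C	1	0.346	0.375	96.27	99.19
rs4923461	BDNF	11	27613486	A	G	0	0.169	0.172	98.33	99.88
rs925946	BDNF	11	27623778	T	G	1	0.347	0.375	98.47	100
rs10501087	BDNF	11	27626684	C	T	1	0.424	0.384	98.00	99.65
rs6265	BDNF	11	27636492	A	G	0	0.461	0.489	98.13	100
rs4074134	BDNFOS	11	27603861	C	G	0	0.185	0.160	98.86	99.54
rs4752856	MTCH2	11	47604618	T	C	0	0.240	0.261	98.40	99.77
rs10838738	MTCH2	11	47619625	G	A	1	0.489	0.455	97.87	99.65
rs7138803	FAIM2	12	48533735	A	G	1	0.354	0.344	98.66	99.42
rs8049439	ATXN2L	16	28745016	C	T	1	0.327	0.356	96.53	100
rs6499640	FTO	16	52327178	G	A	1	0.173	0.173	98.07	99.88
rs1421085	FTO	16	52358455	C	T	0	0.237	0.261	97.87	100
rs1121980	FTO	16	52366748	A	G	0	0.073	0.092	98.93	100
rs8050136	FTO	16	52373776	A	C	0	0.220	0.228	98.86	99.19
rs3751812	FTO	16	52375961	T	G	0	0.381	0.376	98.80	100
rs9939609	FTO	16	52378028	A	T	1	0.174	0.170	98.33	99.88
rs7190492	FTO	16	52386253	A	G	1	0.351	0.351	98.73	99.65
rs8044769	FTO	16	52396636	T	C	1	0.339	0.329	97.33	100
rs1424233	MAF	16	78240252	T	C	1	0.321	0.321	99.13	99.77
rs4788102	SH2B1	16	28780899	A	G	0	0.224	0.204	98.27	99.77
rs17782313	MC4R	18	56002077	C	T	1	0.455	0.464	98.66	100
rs1805081	NPC1	18	19394430	G	A	1	0.343	0.376	98.93	99.65
rs11084753	KCTD15	19	39013977	A	G	1	0.428	0.390	97.93	99.65
rs6013029	CTNNBL1	20	35832994	T	G	1	0.267	0.283	98.27	99.88
rs3813929	HTR2C	X	113724776	T	C	1	0.434	0.399	98.47	99.88
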