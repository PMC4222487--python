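snp_id	gene	cohort	a1	a2	maf	n	beta	se	stat	p
rs9939609	FTO	PIZARRA	A	T	0.398	848	0.875	0.23	3.79	0.0001573
rs9939609	FTO	HORTEGA	A	T	0.435	1345	0.1348	0.15	0.90	0.368
rs9939609	FTO	POOLED	A	T	0.420	2215	0.2976	0.13	2.19	0.0287
rs8044769	FTO	PIZARRA	T	C	0.463	848	-0.582	0.23	-2.54	0.0112
rs8044769	FTO	HORTEGA	T	C	0.455	1331	-0.1019	0.15	-0.68	0.495
rs8044769	FTO	POOLED	T	C	0.458	2198	-0.257	0.13	-1.90	0.0571
rs7190492	FTO	PIZARRA	A	G	0.328	845	-0.559	0.23	-2.34	0.0192
rs7190492	FTO	HORTEGA	A	G	0.337	1346	0.2065	0.16	1.29	0.195
rs7190492	FTO	POOLED	A	G	0.333	2213	-0.07336	0.14	-0.51	0.6076
rs6499640	FTO	PIZARRA	G	A	0.376	847	0.336	0.23	1.43	0.1511
rs6499640	FTO	HORTEGA	G	A	0.381	1347	0.09312	0.15	0.60	0.543
rs6499640	FTO	POOLED	G	A	0.379	2216	0.2335	0.13	1.69	0.0911
rs17782313	MC4R	PIZARRA	C	T	0.199	848	0.575	0.28	1.98	0.0478
rs17782313	MC4R	HORTEGA	C	T	0.191	1348	0.1167	0.19	0.60	0.544
rs17782313	MC4R	POOLED	C	T	0.195	2218	0.3111	0.17	1.80	0.0716
rs10838738	MTCH2	PIZARRA	G	A	0.352	845	0.453	0.24	1.88	0.0603
rs10838738	MTCH2	HORTEGA	G	A	0.353	1348	0.0972	0.15	0.62	0.536
rs10838738	MTCH2	POOLED	G	A	0.353	2215	0.1698	0.14	1.19	0.2318
rs3101336	NEGR1	PIZARRA	A	G	0.375	848	-0.084	0.24	-0.34	0.7277
rs3101336	NEGR1	HORTEGA	A	G	0.343	1348	-0.403	0.15	-2.64	0.0083
rs3101336	NEGR1	POOLED	A	G	0.355	2210	-0.1586	0.14	-1.13	0.2561
rs8049439	ATXN2L	PIZARRA	C	T	0.375	848	-0.139	0.23	-0.58	0.5576
rs8049439	ATXN2L	HORTEGA	C	T	0.338	1344	0.3292	0.15	2.13	0.0331
rs8049439	ATXN2L	POOLED	C	T	0.353	2209	0.1715	0.14	1.22	0.2198
rs3813929	HTR2C	PIZARRA	T	C	0.157	847	-0.406	0.35	-1.16	0.2455
rs3813929	HTR2C	HORTEGA	T	C	0.182	1342	-0.4365	0.23	-1.89	0.0577
rs3813929	HTR2C	POOLED	T	C	0.172	2211	-0.5551	0.20	-2.68	0.0073
rs12654778	ADRB2	PIZARRA	A	G	0.388	848	0.271	0.23	1.16	0.2452
rs12654778	ADRB2	HORTEGA	A	G	0.380	1347	-0.1452	0.15	-0.95	0.339
rs12654778	ADRB2	POOLED	A	G	0.382	2217	0.01463	0.13	0.10	0.9152
rs10913469	SEC16B	PIZARRA	C	T	0.142	848	0.392	0.32	1.21	0.2266
rs10913469	SEC16B	HORTEGA	C	T	0.152	1347	-0.1609	0.20	-0.78	0.432
rs10913469	SEC16B	POOLED	C	T	0.148	2216	0.00939	0.18	0.05	0.96
rs4854344	TMEM18	PIZARRA	G	T	0.172	847	-0.198	0.30	-0.64	0.5173
rs4854344	TMEM18	HORTEGA	G	T	0.169	1348	-0.3012	0.20	-1.48	0.138
rs4854344	TMEM18	POOLED	G	T	0.170	2217	-0.243	0.18	-1.33	0.1815
rs7566605	INSIG2	PIZARRA	C	G	0.327	846	0.101	0.24	0.41	0.676
rs7566605	INSIG2	HORTEGA	C	G	0.321	1348	-0.0301	0.16	-0.18	0.8514
rs7566605	INSIG2	POOLED	C	G	0.322	2216	0.1152	0.14	0.79	0.4265
rs17300539	ADIPOQ	PIZARRA	A	G	0.126	844	-0.072	0.33	-0.21	0.8298
rs17300539	ADIPOQ	HORTEGA	A	G	0.118	1348	0.1146	0.22	0.51	0.6082
rs17300539	ADIPOQ	POOLED	A	G	0.120	2214	0.0818	0.20	0.40	0.6838
rs3774261	ADIPOQ	PIZARRA	A	G	0.495	844	-0.036	0.22	-0.16	0.8727
rs3774261	ADIPOQ	HORTEGA	A	G	0.461	1346	-0.0549	0.15	-0.36	0.7138
rs3774261	ADIPOQ	POOLED	A	G	0.473	2210	0.0609	0.13	0.45	0.6503
rs7647305	ETV5	PIZARRA	T	C	0.205	838	0.022	0.28	0.079	0.9364
rs7647305	ETV5	HORTEGA	T	C	0.215	1325	0.2402	0.18	1.30	0.1927
rs7647305	ETV5	POOLED	T	C	0.213	2175	0.2106	0.16	1.26	0.2077
rs10938397	GNPDA2	PIZARRA	G	A	0.440	848	-0.338	0.22	-1.52	0.1278
rs10938397	GNPDA2	HORTEGA	G	A	0.455	1348	-0.048	0.15	-0.32	0.7492
rs10938397	GNPDA2	POOLED	G	A	0.449	2218	-0.1687	0.13	-1.26	0.2078
rs4712652	PRL	PIZARRA	A	G	0.453	828	0.203	0.23	0.87	0.3846
rs4712652	PRL	HORTEGA	G	A	0.487	1326	0.0367	0.15	0.24	0.8056
rs4712652	PRL	POOLED	A	G	0.489	2175	-0.115	0.13	-0.84	0.3976
rs10508503	PTER	PIZARRA	T	C	0.093	841	-0.119	0.39	-0.30	0.7617
rs10508503	PTER	HORTEGA	T	C	0.112	1315	-0.279	0.23	-1.21	0.2238
rs10508503	PTER	POOLED	T	C	0.105	2174	-0.3695	0.21	-1.71	0.0866
rs925946	BDNF	PIZARRA	T	G	0.282	848	0.128	0.24	0.51	0.6046
rs925946	BDNF	HORTEGA	T	G	0.266	1348	-0.071	0.16	-0.44	0.6578
rs925946	BDNF	POOLED	T	G	0.272	2215	0.0795	0.14	0.54	0.5855
rs10501087	BDNF	PIZARRA	C	T	0.253	845	0.033	0.26	0.12	0.8988
rs10501087	BDNF	HORTEGA	C	T	0.231	1348	0.0875	0.17	0.49	0.6231
rs10501087	BDNF	POOLED	C	T	0.240	2214	0.1472	0.15	0.93	0.3493
rs7138803	FAIM2	PIZARRA	A	G	0.352	844	0.155	0.24	0.65	0.5159
rs7138803	FAIM2	HORTEGA	A	G	0.352	1348	-0.0643	0.15	-0.42	0.675
rs7138803	FAIM2	POOLED	A	G	0.351	2214	0.0513	0.14	0.36	0.7129
rs1424233	MAF	PIZARRA	A	G	0.483	846	-0.192	0.23	-0.83	0.4074
rs1424233	MAF	HORTEGA	G	A	0.499	1348	0.2336	0.14	1.57	0.1158
rs1424233	MAF	POOLED	A	G	0.495	2216	-0.2422	0.13	-1.79	0.0725
rs1805081	NPC1	PIZARRA	G	A	0.329	845	-0.014	0.24	-0.05	0.9553
rs1805081	NPC1	HORTEGA	G	A	0.352	1345	0.0046	0.15	0.03	0.9758
rs1805081	NPC1	POOLED	G	A	0.344	2212	-0.0463	0.14	-0.32	0.7432
rs11084753	KCTD15	PIZARRA	A	G	0.395	846	0.093	0.23	0.39	0.6897
rs11084753	KCTD15	HORTEGA	A	G	0.352	1343	-0.1562	0.15	-1.01	0.31
rs11084753	KCTD15	POOLED	A	G	0.367	2210	0.0573	0.13	0.41	0.6781
rs6013029	CTNNBL1	PIZARRA	T	G	0.091	847	0.014	0.39	0.036	0.9708
rs6013029	CTNNBL1	HORTEGA	T	G	0.066	1348	-0.1522	0.30	-0.50	0.6133
rs6013029	CTNNBL1	POOLED	T	G	0.076	2216	0.1139	0.25	0.44	0.6547
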