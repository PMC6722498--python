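snp_id	chrom	pos	gene	minor_allele	maf	or	ci_low	ci_high	p	source
rs9844493	3	67210593	intergenic	A	0.482	1.59	1.13	2.23	3.74e-3	gwas
rs1320308	5	76875427	S100Z	A	0.447	0.51	0.35	0.73	1.59e-3	gwas
rs6950784	7	155902980	intergenic	G	0.519	1.93	1.37	2.72	4.42e-4	gwas
rs980729	7	98697127	intergenic	A	0.361	0.83	0.59	1.10	1.22e-3	gwas
rs11780345	8	23194453	TNFRSF10A	C	0.196	0.69	0.49	0.97	5.57e-5	gwas
rs11786748	8	27924000	SCARA5	G	0.403	1.95	1.35	2.82	6.18e-4	gwas
rs7988513	13	92232033	GPC5	C	0.300	0.80	0.57	1.14	7.9e-3	gwas
rs1052717	22	41885425	SREBF2	A	0.304	0.36	0.25	0.50	1.36e-7	gwas
rs1894714	22	41953130	LINC00634	T	0.188	4.31	2.65	7.00	7.48e-9	gwas
rs11914200	22	41982066	SEPT3	A	0.239	4.29	2.82	6.55	4.73e-12	gwas
rs8138080	22	42000367	WBP2NL	A	0.261	5.55	3.52	8.75	1.78e-15	gwas
rs7245	22	42085845	NDUFA6	G	0.326	0.28	0.20	0.40	7.52e-13	gwas
rs5751222	22	42121918	NDUFA6-AS1	A	0.229	5.96	3.55	10.00	2.31e-12	gwas
rs5751247	22	42237048	TCF20	C	0.290	4.82	3.09	7.52	2.81e-13	gwas
rs134906	22	42293364	intergenic	T	0.333	0.37	0.26	0.52	2.35e-8	gwas
rs28371725	22	42127803	CYP2D6	T	0.064	2.24	1.11	4.50	6.81e-2	cyp2d6
rs3892097	22	42128945	CYP2D6	T	0.093	6.93	3.92	12.24	1.98e-12	cyp2d6
rs1065852	22	42130692	CYP2D6	A	0.238	6.85	3.98	11.77	3.5e-13	cyp2d6
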