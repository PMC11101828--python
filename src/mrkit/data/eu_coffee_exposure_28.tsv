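variant_id	chrom	pos	gene	effect_allele	other_allele	eaf	beta	se	pvalue	robust	trait	unit
rs4615895	1	96274668	RP11-286B14.1	A	G	0.741	0.012	0.002	4.20e-11	1	coffee intake	cups of coffee per day per allele
rs12989746	2	49368391	FSHR	T	G	0.250	0.010	0.002	2.80e-8	1	coffee intake	cups of coffee per day per allele
rs13387939	2	637498	TMEM18	A	C	0.828	0.017	0.002	9.80e-15	0	coffee intake	cups of coffee per day per allele
rs1527961	2	62780440	PSAT1P2	C	T	0.135	-0.013	0.002	1.70e-8	1	coffee intake	cups of coffee per day per allele
rs780093	2	27742603	GCKR	C	T	0.616	0.013	0.002	1.00e-15	0	coffee intake	cups of coffee per day per allele
rs2189234	4	106075498	TET2	G	T	0.618	0.010	0.002	1.80e-9	1	coffee intake	cups of coffee per day per allele
rs13163336	5	87943710	LINC00461	A	C	0.158	0.015	0.002	1.30e-11	1	coffee intake	cups of coffee per day per allele
rs2465037	6	51179260	RP11-228O6.2	A	C	0.343	-0.011	0.002	4.80e-10	1	coffee intake	cups of coffee per day per allele
rs9398171	6	108983527	FOXO3	T	C	0.711	0.011	0.002	1.10e-9	0	coffee intake	cups of coffee per day per allele
rs34060476	7	73037956	MLXIPL	G	A	0.134	0.018	0.002	7.50e-15	0	coffee intake	cups of coffee per day per allele
rs4410790	7	17284577	AHR	C	T	0.632	0.039	0.002	1.20e-120	1	coffee intake	cups of coffee per day per allele
rs7811609	7	32930597	KBTBD2	T	C	0.375	0.009	0.002	4.00e-8	1	coffee intake	cups of coffee per day per allele
rs442355	8	109128653	AP001331.1	C	G	0.254	-0.011	0.002	1.90e-9	1	coffee intake	cups of coffee per day per allele
rs6469262	8	110443480	PKHD1L1	C	T	0.565	-0.009	0.002	1.90e-8	1	coffee intake	cups of coffee per day per allele
rs78267637	8	33790200	LOC105379364	G	C	0.038	-0.025	0.004	3.90e-9	1	coffee intake	cups of coffee per day per allele
rs61928609	12	11316437	PRH1	C	A	0.835	-0.015	0.002	1.30e-11	1	coffee intake	cups of coffee per day per allele
rs117968677	15	75174251	MPI	A	G	0.024	-0.031	0.006	1.90e-8	1	coffee intake	cups of coffee per day per allele
rs2472297	15	75027880	CYP1A1-CYP1A2	T	C	0.263	0.046	0.002	1.10e-142	1	coffee intake	cups of coffee per day per allele
rs1421085	16	53800954	FTO	C	T	0.404	0.019	0.002	1.70e-29	0	coffee intake	cups of coffee per day per allele
rs57918684	17	60150383	MED13	A	G	0.155	0.013	0.002	8.69e-9	1	coffee intake	cups of coffee per day per allele
rs7224815	17	17845800	TOM1L2	T	A	0.408	-0.011	0.002	3.70e-11	1	coffee intake	cups of coffee per day per allele
rs1942965	18	55032486	ST8SIA3	C	T	0.505	-0.009	0.002	3.80e-8	1	coffee intake	cups of coffee per day per allele
rs4768281	18	57852587	MC4R	C	T	0.237	0.017	0.002	5.60e-20	0	coffee intake	cups of coffee per day per allele
rs630194	18	40950954	SYT4	C	T	0.343	-0.011	0.002	2.30e-11	1	coffee intake	cups of coffee per day per allele
rs75347775	19	18495908	GDF15,MIR3189	A	G	0.245	0.010	0.002	2.70e-8	1	coffee intake	cups of coffee per day per allele
rs6062682	20	62891820	PCMTD2	T	C	0.465	0.010	0.002	2.50e-10	1	coffee intake	cups of coffee per day per allele
rs6063085	20	45840459	ZMYND8	C	A	0.373	0.010	0.002	4.50e-10	1	coffee intake	cups of coffee per day per allele
rs13054099	22	41215672	SLC25A17	C	T	0.261	-0.011	0.002	4.30e-9	1	coffee intake	cups of coffee per day per allele
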