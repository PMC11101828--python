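variant_id	chrom	pos	gene	effect_allele	other_allele	eaf	beta	se	pvalue	robust	trait	unit
rs6681426	1	150586971	MCL1	A	G	0.656	-0.078	0.012	1.06e-10	1	coffee intake	cups of coffee per week per allele
rs1260326	2	27730940	GCKR	T	C	0.56	-0.096	0.011	9.86e-17	0	coffee intake	cups of coffee per week per allele
rs75544042	4	89045331	ABCG2	G	A	0.703	0.069	0.012	4.89e-8	1	coffee intake	cups of coffee per week per allele
rs12189679	6	98333409	MIR2113	G	A	0.637	-0.067	0.012	2.53e-8	0	coffee intake	cups of coffee per week per allele
rs13234378	7	73026151	MLXIPL	A	T	0.896	-0.108	0.019	1.58e-8	1	coffee intake	cups of coffee per week per allele
rs3815455	7	75611756	POR	C	T	0.583	-0.067	0.011	1.12e-8	1	coffee intake	cups of coffee per week per allele
rs4410790	7	17284577	AHR	T	C	0.63	-0.213	0.012	8.08e-68	1	coffee intake	cups of coffee per week per allele
rs662799	11	116663707	APOE5	A	G	0.646	0.066	0.012	4.25e-8	0	coffee intake	cups of coffee per week per allele
rs671	12	112241766	ALDH2	G	A	0.75	-0.354	0.101	3.08e-153	0	coffee intake	cups of coffee per week per allele
rs58806801	15	75059546	CYP1A2,CSK	G	A	0.777	0.084	0.014	2.43e-9	1	coffee intake	cups of coffee per week per allele
rs5760444	22	24878218	ADORA2A-AS1	C	T	0.589	-0.073	0.011	3.70e-10	1	coffee intake	cups of coffee per week per allele
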