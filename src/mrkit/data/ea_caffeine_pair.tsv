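variant_id	chrom	pos	gene	effect_allele	other_allele	eaf	beta	se	pvalue	trait	unit
rs4410790	7	17284577	AHR	T	C	0.630	-0.2130	0.0119	8.08e-68	coffee intake	cups of coffee per week per allele
rs4410790	7	17284577	AHR	T	C	0.637	0.0686	0.0187	2.42e-4	plasma caffeine	SD of plasma caffeine per allele
rs4410790	7	17284577	AHR	T	C	0.622	-0.0049	0.0023	0.03	eGFRcre	SD of eGFR per allele
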