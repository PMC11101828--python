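variant_id	chrom	pos	gene	effect_allele	other_allele	eaf	beta	se	pvalue	trait	unit
rs4410790	7	17284577	AHR	C	T	0.632	0.0391	0.0017	1.20e-120	coffee intake	cups of coffee per day per allele
rs2472297	15	75027880	CYP1A1-CYP1A2	T	C	0.263	0.0465	0.0018	1.10e-142	coffee intake	cups of coffee per day per allele
rs4410790	7	17284577	AHR	C	T	0.631	-0.0631	0.0087	4.03e-13	plasma caffeine	SD of plasma caffeine per allele
rs2472297	15	75027880	CYP1A1-CYP1A2	T	C	0.236	-0.0668	0.0104	1.50e-10	plasma caffeine	SD of plasma caffeine per allele
rs4410790	7	17284577	AHR	C	T	0.630	0.0023	0.0004	1.92e-10	eGFRcre	SD of log(eGFR) per allele
rs2472297	15	75027880	CYP1A1-CYP1A2	T	C	0.260	0.0039	0.0004	8.21e-20	eGFRcre	SD of log(eGFR) per allele
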