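rsid	chrom	gene	allele1	allele2	favorable_allele	consequence	hswa_case_pct	hswa_control_pct
rs11264302	1	ADAM15	A	G	G	intronic	55.8	42.9
rs11548200	1	CCT3	T	C	T	exonic	95.6	89.7
rs699785	1	IGSF3	G	A	A	intronic	30.7	15.5
rs55680124	2	FHL2	C	T	C	ncRNA	88.3	82.9
rs2920503	3	PPARG	C	T	T	intergenic	33.9	25.4
rs13107325	4	SLC39A8	C	T	C	exonic	97.1	91.7
rs205262	6	C6orf106	A	G	A	intronic	79.2	73.0
rs4134943	6	E2F3	C	T	T	intronic	19.0	13.1
rs10452738	7	AUTS2	A	G	A	intronic	75.5	68.3
rs2439823	10	CRTAC1	G	A	A	intronic	54.0	40.9
rs12883788	14	AKAP6	C	T	C	intergenic	56.9	48.4
rs8011870	14	NRXN3	G	A	G	ncRNA	67.2	59.9
rs11881338	19	CRTC1	T	A	A	intronic	57.7	44.0
rs1667369	19	ZNF568	A	C	A	intergenic	75.5	65.5
rs143384	20	GDF5	A	G	G	UTR5	51.1	38.9
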