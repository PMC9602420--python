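rsid	group	pct_11	pct_12	pct_22
rs11264302	case	18.2	51.8	29.9
rs11548200	case	92.0	7.3	0.7
rs699785	case	47.4	43.8	8.8
rs55680124	case	76.6	23.4	0.0
rs2920503	case	45.3	41.6	13.1
rs13107325	case	94.2	5.8	0.0
rs205262	case	62.0	34.3	3.6
rs4134943	case	67.2	27.7	5.1
rs10452738	case	58.4	34.3	7.3
rs2439823	case	20.4	51.1	28.5
rs12883788	case	32.1	49.6	18.2
rs8011870	case	43.8	46.7	9.5
rs11881338	case	18.2	48.2	33.6
rs1667369	case	56.7	38.7	5.1
rs143384	case	22.6	52.6	24.8
rs11264302	control	35.7	42.9	21.4
rs11548200	control	81.7	15.9	2.4
rs699785	control	71.4	26.2	2.4
rs55680124	control	70.6	24.6	4.8
rs2920503	control	55.6	38.1	6.3
rs13107325	control	84.9	13.5	1.6
rs205262	control	56.3	33.3	10.3
rs4134943	control	73.8	26.2	0.0
rs10452738	control	44.4	47.6	7.9
rs2439823	control	34.9	48.4	16.7
rs12883788	control	25.4	46.0	28.6
rs8011870	control	38.9	42.1	19.0
rs11881338	control	31.7	48.4	19.8
rs1667369	control	42.1	46.8	11.1
rs143384	control	38.1	46.0	15.9
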