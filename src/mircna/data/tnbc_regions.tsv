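chrom	cytoband	start	stop	direction	n_cases	denominator	n_genes
chr1	q21.1 - q44	144988715	247737874	gain	5	16	989
chr3	q24 - q29	148802495	194903188	gain	6	16	242
chr5	q11.1 - q22.1	49690172	111370979	loss	5	16	245
chr6	p25.3 - p12.2	2117686	52103799	gain	6	16	609
chr8	q21.3 - q24.3	88884192	146066584	gain	7	16	289
chr10	q23.31 - q26.3	89507004	135372492	loss	4	16	360
chr11	p13 - p11.2	34322106	46565735	gain	5	16	51
chr12	p13.33 - p13.1	309062	14132896	gain	4	16	205
chr13	q12.11 - q14.3	19703703	53876286	loss	5	16	216
chr14	q21.1 - q32.32	38723471	103447263	loss	4	16	485
chr15	q26.1 - q26.3	90276459	102241406	gain	4	16	63
chr16	q11.2 - q22.1	46693731	67933130	loss	4	16	169
chr17	q24.2 - q25.3	65989022	80993001	gain	5	16	232
chr19	p13.11 - p12	18266482	21108358	gain	4	16	66
chrX	p22.33 - p11.21	1314894	58051765	loss	5	16	364
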