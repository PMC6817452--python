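chrom	cytoband	start	stop	direction	n_cases	denominator	n_genes
chr1	q21.1 - q44	145103876	249118400	gain	9	14	1029
chr6	p22.3 - p21.1	18093033	43409896	gain	5	14	458
chr7	q11.21 - q36.3	62516153	158909738	gain	6	14	687
chr8	q21.13 - q24.3	82193925	146280020	gain	7	14	324
chr17	q21.32 - q25.3	46048958	81029941	gain	5	14	445
chr19	p13.11	17845278	17927374	gain	4	14	4
chr20	q13.31 - q13.33	55212094	62893189	gain	5	14	114
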