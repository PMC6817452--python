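mirna	cytoband	start	stop	cna_direction	expression_direction	log2fc	adj_p
hsa-miR-135b-5p	1q32.1	205448302	205448398	gain	up	1.93	0.001
hsa-miR-944	3q28	189829922	189830009	gain	up	1.13	0.004
hsa-miR-548p	5q21.1	100816482	100816565	loss	down	-0.53	0.002
hsa-miR-1275	6p21.31	33999972	34000051	gain	up	0.61	0.049
hsa-miR-607	10q24.1	96828669	96828764	loss	down	-0.50	0.006
hsa-miR-608	10q24.31	100974985	100975084	loss	down	-0.52	0.04
hsa-miR-378c	10q26.3	130962588	130962668	loss	down	-0.42	0.024
hsa-miR-129-2-3p	11p11.2	43581394	43581483	gain	up	0.77	0.036
hsa-miR-1260a	14q24.3	77266218	77266290	loss	down	-3.30	0.004
hsa-miR-342-3p	14q32.2	100109655	100109753	loss	down	-1.51	0.039
hsa-miR-323a-5p	14q32.31	101025732	101025817	loss	down	-0.59	0.001
hsa-miR-539-5p	14q32.31	101047321	101047398	loss	down	-0.68	0.05
hsa-miR-668	14q32.31	101055258	101055323	loss	down	-0.45	0.014
hsa-miR-323b-3p	14q32.31	101056219	101056300	loss	down	-0.49	0.008
hsa-miR-323b-5p	14q32.31	101056219	101056300	loss	down	-0.49	0.009
hsa-miR-634	17q24.2	66787072	66787168	gain	up	0.90	0.005
hsa-miR-188-5p	Xp11.23	50003503	50003588	loss	down	-0.93	0.02
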