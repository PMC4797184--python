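# Published network summaries for ten BioGRID protein interaction networks
# (giant connected components) and four Homo sapiens experimental subnetworks.
# Columns: network id, tax id (or "subnetwork"), n nodes, m edges, published
# edge density (truncated at the printed digits).
network	tax_id	n	m	density
house_mouse	10090	5057	11560	0.000904
norway_rat	10116	1710	2582	0.001767
candida_albicans	237561	304	316	0.006860
s_pombe	284812	3854	55054	0.007414
p_falciparum	36329	1172	2415	0.003519
a_thaliana	3702	7103	17752	0.000703
s_cerevisiae	559292	6008	227836	0.01262
c_elegans	6239	3701	7695	0.0011
d_melanogaster	7227	8017	38973	0.0012
h_sapiens	9606	15795	159278	0.001276
affinity_chromatography	subnetwork	13124	82900	0.000962
two_hybrid	subnetwork	9844	37280	0.000769
biochemical	subnetwork	3686	20083	0.00295
pull_down	subnetwork	5714	10957	0.00067
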