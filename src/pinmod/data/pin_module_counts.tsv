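# Published numbers of modules detected per method on the ten protein
# interaction networks.  The published table prints the digits of some rows
# run together; this file carries the segmentation that is uniquely
# consistent with (a) one-module partitions having Q = 0, (b) the walktrap
# column being maximal except for Candida albicans, (c) the published
# Homo sapiens ratios (walktrap = 38x fast-greedy, 163x spinglass) and
# (d) the published regression significances of the Q-vs-count fits.
network	dm-pearson	dm-spearman	dsp-pearson	dsp-spearman	fastgreedy	labelprop	multilevel	spinglass	walktrap
house_mouse	9	8	10	6	71	95	28	25	360
norway_rat	26	44	25	5	28	56	28	25	123
candida_albicans	16	14	12	14	14	11	14	12	13
s_pombe	5	11	2	2	20	5	8	13	582
p_falciparum	15	16	25	26	18	4	22	22	179
a_thaliana	15	13	20	14	57	190	36	25	390
s_cerevisiae	14	10	8	13	5	2	8	10	319
c_elegans	10	6	9	6	38	51	29	25	351
d_melanogaster	21	21	20	19	55	24	29	25	884
h_sapiens	30	20	34	63	89	3	13	21	3425
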