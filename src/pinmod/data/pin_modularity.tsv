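# Published per-network modularity Q of the nine module detection methods on
# ten BioGRID protein interaction networks (giant connected components).
network	dm-pearson	dm-spearman	dsp-pearson	dsp-spearman	fastgreedy	labelprop	multilevel	spinglass	walktrap
house_mouse	0.4903	0.4168	0.4281	0.3999	0.5647	0.4578	0.6066	0.6239	0.5265
norway_rat	0.5061	0.2901	0.4985	0.4948	0.6608	0.5089	0.6682	0.6683	0.5951
candida_albicans	0.4571	0.4629	0.4625	0.4629	0.4757	0.428	0.4757	0.4728	0.4689
s_pombe	0.1669	0.1673	0.1005	0.128	0.2396	3e-04	0.2516	0.268	0.1545
p_falciparum	0.4775	0.4576	0.4713	0.466	0.5171	0.0066	0.5222	0.5396	0.3505
a_thaliana	0.6635	0.6004	0.5824	0.5781	0.6893	0.6977	0.7296	0.742	0.6822
s_cerevisiae	0.2108	0.2055	0.0399	0.0283	0.2557	1e-04	0.2532	0.2741	0.2221
c_elegans	0.5141	0.5087	0.5023	0.4989	0.6042	0.1872	0.6106	0.6231	0.5268
d_melanogaster	0.4509	0.4491	0.4124	0.4238	0.471	0.2608	0.5232	0.5307	0.3865
h_sapiens	0.2045	0.0898	0.0708	0.0655	0.2877	1e-04	0.3498	0.3612	0.253
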