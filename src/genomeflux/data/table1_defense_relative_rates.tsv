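# Relative rates of genome dynamics events in defense systems vs all genes,
# one row per ATGC (alignable tight genome cluster); ratios are
# (DS events / N_DS COGs) / (all events / N_ALL COGs), dimensionless.
atgc	genus	gain_ratio	loss_ratio	expansion_ratio	reduction_ratio	all_gde_ratio
ATGC149	Acinetobacter	1.73	1.31	1.09	1.89	1.39
ATGC014	Bacillus	1.06	1.18	0.71	1.16	1.13
ATGC015	Bacillus	1.17	1.68	0.62	0.73	1.47
ATGC104	Bifidobacterium	1.22	1.31	0.59	0.43	1.22
ATGC105	Bifidobacterium	1.90	1.73	0.55	1.11	1.76
ATGC144	Borrelia	0.78	1.63	1.12	1.71	1.51
ATGC136	Brucella-Ochrobactrum	1.20	0.45	0.02	0.19	0.70
ATGC088	Burkholderia	1.76	0.76	1.18	0.78	0.91
ATGC089	Burkholderia	1.34	1.24	0.24	0.51	1.20
ATGC143	Campylobacter	1.16	1.92	1.37	1.99	1.77
ATGC044	Candidatus-Rickettsia	1.01	1.44	1.22	1.85	1.34
ATGC021	Chlamydia	0.20	0.68	0.01	0.82	0.65
ATGC022	Chlamydia-Chlamydophila	0.01	0.79	1.01	0.26	0.54
ATGC081	Clostridium	1.70	1.36	1.04	2.59	1.40
ATGC067	Corynebacterium	1.46	1.17	0.70	1.08	1.19
ATGC068	Corynebacterium	1.18	1.89	1.44	1.33	1.79
ATGC002	Enterobacter-Klebsiella	1.40	1.85	1.10	3.14	1.63
ATGC001	Enterobacteria	1.18	1.98	1.61	3.51	1.88
ATGC138	Francisella	1.46	1.63	0.59	2.86	1.59
ATGC050	Helicobacter	1.22	2.90	3.15	4.97	2.63
ATGC056	Lactobacillus	1.58	1.34	0.75	1.17	1.36
ATGC184	Legionella	2.13	1.75	1.19	1.92	1.78
ATGC108	Listeria	1.23	2.69	0.42	2.29	2.29
ATGC024	Mycobacterium	0.84	1.38	0.88	0.54	1.16
ATGC032	Mycoplasma	0.34	1.51	1.29	0.19	1.32
ATGC137	Neisseria	1.35	1.18	1.43	0.76	1.22
ATGC159	Propionibacterium	1.86	0.72	1.05	0.17	0.93
ATGC071	Pseudomonas	1.54	1.45	0.69	0.96	1.42
ATGC120	Shewanella	2.87	0.99	1.31	2.52	1.34
ATGC052	Staphylococcus	1.06	1.22	0.73	1.65	1.21
ATGC003	Streptococcus	1.11	1.02	2.03	0.68	1.05
ATGC004	Streptococcus	1.29	1.45	1.48	1.57	1.42
ATGC005	Streptococcus	1.36	1.64	0.69	1.54	1.49
ATGC093	Sulfolobus	0.96	1.66	1.55	1.62	1.55
ATGC134	Xanthomonas	1.11	2.19	1.43	3.01	1.71
ATGC127	Yersinia	1.29	1.38	1.20	1.21	1.34
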