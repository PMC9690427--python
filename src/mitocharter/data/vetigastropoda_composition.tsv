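Species	Length	A%	T%	G%	C%	AT_skew	GC_skew	AT_content
Entemnotrochus rumphii	15795	35.21	29.98	14.43	20.39	0.080225	-0.17112	65.19
Pseudorimula sp.	16682	28.76	29.79	14.47	26.98	-0.01751	-0.30181	58.55
Lepetodrilus schrolli	15579	29.39	32.79	14.90	22.93	-0.05473	-0.21236	62.18
Haliotis rufescens	16646	35.39	24.93	13.75	25.93	0.173389	-0.30719	60.32
Haliotis rubra	16907	34.57	24.55	14.18	26.70	0.169502	-0.30623	59.11
Fissurella volcano	17575	25.72	35.83	26.69	11.77	-0.16431	0.387985	61.54
Diodora graeca	17209	21.75	36.01	29.44	12.80	-0.24688	0.394139	57.76
Granata lyrata	17632	33.39	24.68	14.93	27.00	0.150029	-0.28778	58.07
Tegula rustica	17799	33.32	33.53	15.64	17.51	-0.00311	-0.05643	66.84
Tegula nigerrima	17755	33.58	33.44	15.52	17.46	0.002101	-0.05874	67.02
Phasianella solida	16698	30.41	31.63	22.13	15.83	-0.01967	0.166089	62.04
Phasianella australis	18397	30.89	34.95	20.00	14.16	-0.06159	0.171042	65.84
Steromphala umbilicalis	16277	34.74	32.44	13.09	19.72	0.034199	-0.20202	67.19
Monodonta labio	16440	31.51	27.74	13.97	26.77	0.063655	-0.31412	59.25
Umbonium thomasi	15998	34.85	29.13	13.96	22.06	0.089399	-0.22471	63.98
Bolma rugosa	17432	34.06	34.72	15.37	15.85	-0.0096	-0.01544	68.77
Lunella correensis	17308	31.03	35.30	19.93	13.74	-0.06437	0.1838	66.33
Astralium haematragum	16310	33.30	33.68	16.25	16.76	-0.00567	-0.0156	66.99
Angaria neglecta	19470	28.86	36.39	22.28	12.47	-0.11533	0.282377	65.25
Angaria delphinus	19554	28.20	36.12	22.51	13.18	-0.12309	0.261393	64.31
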