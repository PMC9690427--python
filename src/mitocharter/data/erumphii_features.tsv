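Gene	From	To	Length	Start	Stop	Anticodon	Intergenic	Strand
cox1	1	1536	1536	ATG	TAA		4	H
cox2	1562	2254	693	ATG	TAA		25	H
tRNA-Asp	2283	2351	69			GTC	28	H
atp8	2352	2516	165	ATG	TAA		0	H
atp6	2539	3237	699	ATG	TAG		22	H
tRNA-Phe	3282	3348	67			GAA	44	L
nad5	3359	5089	1731	ATG	TAA		10	L
tRNA-His	5090	5155	66			GTG	0	L
nad4	5162	6541	1380	ATG	TAA		6	L
nad4l	6535	6834	300	ATG	TAG		-7	L
tRNA-Thr	6842	6907	66			TGT	7	H
tRNA-Ser(UCA)	6907	6973	67			TGA	-1	L
cytb	6984	8123	1140	ATG	TAA		10	L
nad6	8149	8646	498	ATG	TAG		25	L
tRNA-Pro	8647	8714	68			TGG	0	L
nad1	8735	9670	936	ATG	TAG		20	L
tRNA-Leu(UUA)	9671	9738	68			TAA	0	L
tRNA-Leu(CUA)	9743	9810	68			TAG	4	L
16S RNA	9811	11,196	1386				0	L
tRNA-Val	11,197	11,265	69			TAC	0	L
12S RNA	11,266	12,159	894				0	L
tRNA-Met	12,160	12,227	68			CAT	0	L
tRNA-Tyr	12,267	12,333	67			GTA	39	L
tRNA-Cys	12,341	12,404	64			GCA	7	L
tRNA-Trp	12,405	12,471	67			TCA	0	L
tRNA-Gln	12,472	12,536	65			TTG	0	L
tRNA-Gly	12,552	12,621	70			TCC	15	L
tRNA-Glu	12,636	12,700	65			TTC	14	L
cox3	13,065	13,844	780	ATG	TAA		364	H
tRNA-Lys	13,909	13,974	66			TTT	64	H
tRNA-Ala	13,988	14,053	66			TGC	13	H
tRNA-Arg	14,054	14,121	68			TCG	0	H
tRNA-Asn	14,132	14,197	66			GTT	10	H
tRNA-Ile	14,199	14,263	65			GAT	1	H
nad3	14,264	14,617	354	ATG	TAA		0	H
tRNA-Ser(AGC)	14,624	14,693	70			GCT	6	H
nad2	14,694	15,791	1098	ATG	TAA		0	H
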