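species	accession	gc_percent	UAA_heg	UAA_leg	UAG_heg	UAG_leg	UGA_heg	UGA_leg
Microcystis aeruginosa	NC_010296	42.331	0.41	0.19	0.26	0.5	0.33	0.2
Bacillus anthracis	NC_005945	35.379	0.77	0.24	0.34	0.26	0.31	0.21
Bacillus subtilis	NC_000964	43.514	0.63	0.21	0.2	0.13	0.32	0.33
Staphylococcus aureus	NC_002758	32.878	0.79	0.35	0.36	0.33	0.49	0.40
Listeria monocytogenes	NC_003210	37.981	0.53	0.28	0.2	0.22	0.32	0.35
Streptococcus pyogenes	NC_002737	38.512	0.59	0.23	0.31	0.28	0.52	0.45
Lactococcus lactis	NC_002662	35.329	0.64	0.23	0.34	0.37	0.34	0.32
Deinococcus deserti	NC_002937	63.388	0.17	0.10	0.10	0.12	0.14	0.18
Bacteroides thetaiotaomicron	NC_004663	42.837	0.66	0.33	0.36	0.21	0.45	0.33
Escherichia coli	NC_000913	50.791	0.62	0.3	0.42	0.27	0.7	0.39
Salmonella enterica	NC_003197	52.222	0.57	0.35	0.36	0.27	0.6	0.35
Yersinia pestis	NC_003143	47.636	0.63	0.35	0.39	0.31	0.66	0.45
Shewanella oneidensis	NC_004347	45.961	0.7	0.29	0.32	0.27	0.43	0.36
Neisseria meningitidis	NC_003112	51.528	0.52	0.14	0.32	0.28	0.56	0.25
Legionella pneumophila	NC_002942	38.27	0.37	0.39	0.33	0.27	0.39	0.29
Acidithiobacillus ferrooxidans	NC_011761	58.773	0.28	0.29	0.16	0.19	0.32	0.26
Campylobacter jejuni	NC_002163	30.549	0.47	0.25	0.32	0.32	0.34	0.42
Desulfovibrio vulgaris	NC_002937	63.388	0.18	0.2	0.18	0.2	0.27	0.22
Mycobacterium tuberculosis	NC_000962	65.615	0.19	0.16	0.18	0.2	0.21	0.26
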