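sncRNA	group	Me	log2_Me	log2_Q1	log2_Q3	p_I_vs_III_IV	p_I_vs_II	p_II_vs_III_IV
hsa_piR_011291	I	3.3173	1.73	0.38	2.38	0.023651
hsa_piR_011291	III+IV	1.6245	0.7	-0.31	1.14
hsa_piR_011291	II	1.3104	0.39	-0.4	0.9
hsa_piR_019122	I	13.0864	3.71	2.56	4.6	0.043099
hsa_piR_019122	III+IV	6.9163	2.79	2.11	3.31
hsa_piR_019122	II	5.5022	2.46	2.26	2.87
hsa_piR_001311	I	4.1699	2.06	0.98	2.73	0.003247
hsa_piR_001311	III+IV	0.9862	-0.02	-1.86	1.09
hsa_piR_001311	II	1.5801	0.66	-0.79	2.09
hsa_piR_015026	I	2.1435	1.1	-0.95	2.67	0.030825
hsa_piR_015026	III+IV	0.5987	-0.74	-1.47	-0.08
hsa_piR_015026	II	0.4033	-1.31	-1.56	-1.01
hsa_piR_015462	I	7.9447	2.99	0.65	3.67	0.003247	0.015984
hsa_piR_015462	III+IV	1.0210	0.03	-0.58	0.62
hsa_piR_015462	II	0.7022	-0.51	-1.14	-0.04
hsa_piR_016735	I	4.1699	2.06	1.41	2.66	0.013416
hsa_piR_016735	III+IV	1.8404	0.88	0.3	1.58
hsa_piR_016735	II	1.6358	0.71	-0.54	0.81
hsa_piR_019675	I	28.2465	4.82	2.58	7.2	<0.001	<0.001	0.031124
hsa_piR_019675	III+IV	1.2834	0.36	-0.33	1.01
hsa_piR_019675	II	0.7900	-0.34	-0.67	0.01
hsa_piR_020381	I	2.8089	1.49	1.14	2.88	0.003247	0.002997
hsa_piR_020381	III+IV	1.3104	0.39	0.04	1.26
hsa_piR_020381	II	1.0792	0.11	-0.12	0.35
hsa_piR_020485	I	1.1567	0.21	-2.27	1.37	0.001523
hsa_piR_020485	III+IV	0.0171	-5.87	-13.71	-2.95
hsa_piR_020485	II	0.0349	-4.84	-6.64	-1.78
hsa_piR_004880	I	4.2871	2.1	0.65	2.34	<0.001	0.004745
hsa_piR_004880	III+IV	0.9266	-0.11	-0.36	0.09
hsa_piR_004880	II	0.9659	-0.05	-0.21	0.04
hsa_piR_000807	I	0.1975	-2.34	-5.62	0.53	0.012145
hsa_piR_000807	III+IV	0.0013	-9.55	-13.58	-2.43
hsa_piR_000807	II	0.0011	-9.89	-12.96	-3.85
hsa-let-7b-5p	I	230.7201	7.85	4.59	9.13	0.00462
hsa-let-7b-5p	III+IV	13.6422	3.77	1.58	5.26
hsa-let-7b-5p	II	6.6346	2.73	-5.2	6.07
hsa-let-7i-5p	I	5.2416	2.39	2.15	2.95	0.001976		0.006596
hsa-let-7i-5p	III+IV	2.1735	1.12	0.79	1.49
hsa-let-7i-5p	II	3.5554	1.83	1.72	2.58
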