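sncRNA	150	118	154	170	176	147	124	157	206	200	127	177	134	207
hsa_piR_011291	69	80	58	40	29	27	26	4	69	53	24	42	17	55
hsa_piR_019122	42	23	54	31	5	7	19	8	11	9	7	12	5	35
hsa_piR_001311	150	66	150	207	15	78	96	21	87	81	54	87	75	48
hsa_piR_015026	120	65	140	185	15	55	75	10	35	70	80	110	45	15
hsa_piR_015462	1290	1302	1688	1156	392	884	1764	428	1046	668	700	1068	594	1102
hsa_piR_016735	170	232	265	174	106	207	221	35	155	176	85	178	40	104
hsa_piR_019675	2563	2074	4699	1865	947	1639	2913	661	1941	1823	1185	1392	663	1847
hsa_piR_020381	9635	7413	14019	6381	5229	7449	5778	1965	6726	6621	3318	4833	1497	5532
hsa_piR_020485	170	250	340	1078	147	525	672	182	672	448	343	357	560	532
hsa_piR_004880	754	651	839	568	195	439	878	213	518	333	347	532	297	549
hsa_piR_000807	1290	1300	1684	1156	392	880	1760	428	1046	668	700	1064	594	1102
hsa_piR_001312	450	198	450	621	54	234	288	63	261	252	162	261	234	144
hsa_piR_020365	56	53	40	97	19	13	46	11	53	47	8	11	14	9
hsa_piR_022628	28	119	133	28	42	175	21	7	21	28	0	14	28	14
hsa_piR_022104	200	314	471	628	0	0	471	0	0	157	157	0	0	1099
hsa_piR_019752	135	243	45	90	9	108	18	9	108	81	36	45	18	72
hsa_piR_019269	33	23	55	31	5	7	19	8	11	9	7	12	5	35
hsa_piR_006927	32	23	54	31	5	7	19	8	11	9	7	12	5	35
hsa_piR_002769	10	82	164	41	0	0	0	0	0	0	0	0	0	0
hsa_piR_008112	14	7	9	0	0	0	1	0	14	7	0	0	0	0
hsa_piR_006710	18	16	24	16	2	4	14	0	4	4	14	10	2	20
hsa_piR_010119	35	78	83	43	21	56	41	30	35	64	17	24	36	29
hsa_piR_020668	30	53	192	84	17	24	25	6	41	28	26	45	25	71
hsa_piR_018552	17	6	18	11	2	7	12	3	10	7	7	5	5	11
hsa-let-7b-5p	35	29	32	41	11	9	34	9	6	2	20	9	32	17
hsa-let-7i-5p	29	23	26	10	26	10	24	0	1	1	14	14	30	18
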