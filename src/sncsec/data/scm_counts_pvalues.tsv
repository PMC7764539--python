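sncRNA	p_I_vs_III_IV	p_II_vs_III_IV
hsa_piR_011291	0.017	0.004
hsa_piR_019122	0.001	0.054
hsa_piR_001311	0.029	0.372
hsa_piR_015026	0.041	0.349
hsa_piR_015462	0.047	0.038
hsa_piR_016735	0.039	0.107
hsa_piR_019675	0.023	0.064
hsa_piR_020381	0.004	0.061
hsa_piR_020485	0.052	0.148
hsa_piR_004880	0.029	0.023
hsa_piR_000807	0.046	0.038
hsa_piR_001312	0.031	0.377
hsa_piR_020365	0.055	0.410
hsa_piR_022628	0.003	0.424
hsa_piR_022104	0.048	0.311
hsa_piR_019752	0.023	0.165
hsa_piR_019269	0.001	0.073
hsa_piR_006927	0.001	0.076
hsa_piR_002769	0.006	0.099
hsa_piR_008112	0.042	0.004
hsa_piR_006710	0.005	0.037
hsa_piR_010119	0.023	0.120
hsa_piR_020668	0.038	0.207
hsa_piR_018552	0.027	0.103
hsa-let-7b-5p	0.036	0.164
hsa-let-7i-5p	0.045	0.065
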