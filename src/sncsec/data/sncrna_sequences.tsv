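sncRNA	accession	sequence	annealing_temp_c
hsa_piR_011291	DQ585247	TGCGACTCACTGTAGTGCTGGGGATCC	46.2
hsa_piR_019122	DQ596252	GACAGAGAAAACAAGGTGGTGAACTATGCCC	46.2
hsa_piR_001311	DQ571812	ATTGGTGGTTCAGTGGTAGAATTCTCGCC	45
hsa_piR_015026	DQ590548	TGGTTCAGTGGTAGAATTCTCGCCTCC	45
hsa_piR_015462	DQ591122	CCTGGGCCAGCCTGATGATGTCCTCCTC	45
hsa_piR_016735	DQ593039	CCTGGGAATACCGGGTGCTGTAGGCTTA	50
hsa_piR_019675	DQ596992	GCAATAACAGGTCTGTGATGCCCTTAGA	53
hsa_piR_020381	DQ597997	GGCGGGAGTAACTATGACTCTCTTAAGGTA	53
hsa_piR_020485	DQ598159	GATGTAGCTCAGTGGTAGAGCGCATGCT	53
hsa_piR_004880	DQ576715	TTGTCCTGGACCAGCCTGATGATGTCCTC	45
hsa_piR_000807	DQ571005	CTGATGATGTCCTCCTCCAGTTGCCGC	53
hsa_piR_001312	DQ571813	ATTGGTGGTTCAGTGGTAGAATTCTCGCCTG	46.2
hsa_piR_020365	DQ597975	GGCCGTGATCGTATAGTGGTTAGTACTCTG	46.2
hsa_piR_022628	DQ600952	TAGAGCATGAGACTCTTAATCTCAGGGTCGTG	48.9
hsa_piR_022104	DQ600278	TACCTAGGTGATGGGATGATCTGTGC	48.9
hsa_piR_020388	DQ598008	GGCTCGTTGGTCTAGGGGTATGATTCTCGG	45
hsa_piR_019752	DQ597110	GCAGAGTGGCGCAGCGGAAGCGTGCTGGGCCC	61.6
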