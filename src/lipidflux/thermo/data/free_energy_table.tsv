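environment	species_from	species_to	dg_kcal_mol	err_kcal_mol
2:1:1	POPE	POPC	1	1
2:1:1	POPE	POPG	-17	2
3:1_PC_PG	POPE	POPC	-1	1
3:1_PC_PG	POPE	POPG	-21	3
POPC	POPE	POPC	-1	1
POPC	POPE	POPG	-17	1
WT_CA	POPE	POPC	5	1
WT_CA	POPE	POPG	-19	2
ELIC5_CA	POPE	POPC	3	1
ELIC5_CA	POPE	POPG	-24	2
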