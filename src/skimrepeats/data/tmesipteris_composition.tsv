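repeat_type	lineage	level	tannensis_pct	obliqua_pct
Ty1/Copia		top	14.13	16.45
Ty1/Copia	SIRE	lineage	0.11	0.06
Ty1/Copia	Ale	lineage	1.45	1.40
Ty1/Copia	Ivana	lineage	5.00	4.51
Ty1/Copia	Tork	lineage	4.54	7.99
Ty1/Copia	Other	lineage	3.03	2.48
Ty3/Gypsy		top	9.36	9.07
Ty3/Gypsy	Tekay	lineage	0.26	0.10
Ty3/Gypsy	Athila	lineage	8.79	8.01
Ty3/Gypsy	Reina	lineage	0.00	0.04
Ty3/Gypsy	Other	lineage	0.32	0.93
LTR-unclassified		top	1.86	2.65
LINE		top	4.91	4.04
DNA transposons		top	3.39	4.27
DNA transposons	TIR/EnSpm-CACTA	lineage	1.62	1.65
DNA transposons	TIR/haT	lineage	1.68	2.62
DNA transposons	Helitron	lineage	0.09	0.00
rDNA		top	0.23	0.27
Satellite		top	6.47	8.04
Unclassified		top	14.61	15.49
Small unclassified clusters (GP < 0.01%)		top	14.31	16.97
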