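gene	species	clade	1	2	3	4	5	6	7	8-ABCB1	8-ABCB19	9
LOC_Os08g45030	Oryza_sativa	ABCB1	A	A	A	A	P	A	P	A	A	A
LOC_Os04g38570	Oryza_sativa	ABCB19	P	P	P	P	P	P	P	A	P	P
AT2G36910	Arabidopsis_thaliana	ABCB1	P	P	P	P	P	P	P	P	A	P
AT3G28860	Arabidopsis_thaliana	ABCB19	P	P	P	P	P	P	P	A	P	P
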