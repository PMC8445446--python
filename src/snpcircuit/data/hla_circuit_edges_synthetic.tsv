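rsid	gene_symbol	cluster	direction	n_tissues
rs886424	CCHCR1	1	up	9
rs886424	PSORS1C1	1	down	3
rs886424	WASF5P	1	up	1
rs886424	HLA-A	2	up	1
rs886424	HLA-C	2	up	2
rs886424	HLA-G	2	up	1
rs886424	FLOT1	2	up	3
rs886424	PPP1R18	2	up	1
rs886424	LINC00243	2	up	1
rs886424	HLA-K	2	up	1
rs886424	NOTCH4	2	up	1
rs3129716	HLA-DRB1	3	down	1
rs3129716	HLA-DRB5	3	down	1
rs3129716	HLA-DQB1	3	down	9
rs3129716	HLA-DQB2	3	up	7
rs3129716	HLA-DMA	3	up	8
rs3129716	HLA-DMB	3	up	1
rs3129716	CYP21A2	4	up	7
rs3129716	CYP21A1P	4	down	26
rs3129716	TNXA	4	down	1
rs3129716	STK19B	4	down	1
rs3129716	C4A	4	down	29
rs3129716	C4B	4	up	4
rs3129716	VARS2	4	up	1
rs3129716	RNF5	4	up	1
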