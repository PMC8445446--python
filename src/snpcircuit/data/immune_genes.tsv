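ensembl_id	symbol	name	note	category	high_prob_snps	hclust_group
ENSG00000204520.8	MICA	MHC class I polypeptide-related sequence A	HLA locus	antigen_presentation	-	3
ENSG00000204525.10	HLA-C	Major histocompatibility complex, class I, C	HLA locus	antigen_presentation	rs886424,rs1264361	7
ENSG00000206503.7	HLA-A	Major histocompatibility complex, class I, A	HLA locus	antigen_presentation	rs886424,rs1264361	7
ENSG00000204632.7	HLA-G	Major histocompatibility complex, class I, G	HLA locus	antigen_presentation	rs886424,rs1264361	7
ENSG00000204516.5	MICB	MHC class I polypeptide-related sequence B	HLA locus	antigen_presentation	-	8
ENSG00000196126.6	HLA-DRB1	Major histocompatibility complex, class II, DR beta 1	HLA locus	antigen_presentation	rs3129716,rs9268606	8
ENSG00000237541.3	HLA-DQA2	Major histocompatibility complex, class II, DQ alpha 2	HLA locus	antigen_presentation	rs9268606	8
ENSG00000232629.4	HLA-DQB2	Major histocompatibility complex, class II, DQ beta 2	HLA locus	antigen_presentation	rs3129716,rs9268606	8
ENSG00000204257.10	HLA-DMA	Major histocompatibility complex, class II, DM alpha	HLA locus	antigen_presentation	rs3129716	8
ENSG00000242574.4	HLA-DMB	Major histocompatibility complex, class II, DM beta	HLA locus	antigen_presentation	rs3129716	8
ENSG00000196735.7	HLA-DQA1	Major histocompatibility complex, class II, DQ alpha 1	HLA locus	antigen_presentation	rs9268606	8
ENSG00000179344.12	HLA-DQB1	Major histocompatibility complex, class II, DQ beta 1	HLA locus	antigen_presentation	rs3129716,rs9268606	8
ENSG00000198502.5	HLA-DRB5	Major histocompatibility complex, class II, DR beta 5	HLA locus	antigen_presentation	rs3129716	8
ENSG00000176920.10	FUT2	Fucosyltransferase 2	H antigen	antigen_presentation	-	21
ENSG00000223534.1	HLA-DQB1-AS1	HLA-DQB1 antisense RNA 1	Non-coding RNA	antigen_presentation	-	8
ENSG00000176998.3	HCG4	HLA complex group 4	Non-coding RNA	antigen_presentation	-	15
ENSG00000206337.6	HCP5	HLA complex P5	Non-coding RNA	antigen_presentation	-	8
ENSG00000103811.11	CTSH	Cathepsin H	Proteinase	antigen_presentation	-	8
ENSG00000204622.6	HLA-J	Major histocompatibility complex, class I, J (pseudogene)	Pseudogene	antigen_presentation	-	7
ENSG00000230795.2	HLA-K	Major histocompatibility complex, class I, K (pseudogene)	Pseudogene	antigen_presentation	rs886424,rs1264361	7
ENSG00000229391.3	HLA-DRB6	Major histocompatibility complex, class II, DR beta 6 (pseudogene)	Pseudogene	antigen_presentation	rs9268606	8
ENSG00000196301.3	HLA-DRB9	Major histocompatibility complex, class II, DR beta 9 (pseudogene)	Pseudogene	antigen_presentation	rs9268606	8
ENSG00000237669.1	HCG4P3	HLA complex group 4 pseudogene	Pseudogene	antigen_presentation	-	11
ENSG00000173531.11	MST1	Macrophage stimulating 1	-	immune_signaling	rs11715915,rs6997,rs9814873	10
ENSG00000133466.9	C1QTNF6	C1q and TNF related 6	B-cell receptor	immune_signaling	rs229544	3
ENSG00000178188.10	SH2B1	SH2B adaptor protein 1	Cytokine receptor	immune_signaling	rs4788084,rs62031562,rs743590,rs762633	1
ENSG00000105397.9	TYK2	Tyrosine kinase 2	Cytokine	immune_signaling	-	7
ENSG00000197272.2	IL27	Interleukin 27	Cytokine	immune_signaling	rs4788084,rs62031562,rs743590,rs762633	10
ENSG00000204616.6	TRIM31	Tripartite motif containing 31	Cytokine	immune_signaling	-	20
ENSG00000160856.16	FCRL3	Fc receptor like 3	Fc receptor-like	immune_signaling	-	7
ENSG00000240053.8	LY6G5B	Lymphocyte antigen 6 family member G5B	Glycophosphatidylinositol	immune_signaling	-	1
ENSG00000204421.2	LY6G6C	Lymphocyte antigen 6 family member G6C	Glycophosphatidylinositol	immune_signaling	-	16
ENSG00000156711.12	MAPK13	Mitogen-activated protein kinase 13	Inflammation	immune_signaling	-	16
ENSG00000111540.11	RAB5B	RAB5B, member RAS oncogene family	SMAD	immune_signaling	rs10876870,rs4759229	3
ENSG00000166949.11	SMAD3	SMAD family member 3	SMAD	immune_signaling	-	3
ENSG00000005020.8	SKAP2	Src kinase associated phosphoprotein 2	Src	immune_signaling	-	2
ENSG00000184293.3	CLECL1	C-type lectin like 1	T cell costimulator	immune_signaling	-	8
ENSG00000119919.9	NKX2-3	NK2 homeobox 3	T cell differentiation, TF	immune_signaling	-	12
ENSG00000213658.6	LAT	Linker for activation of T cells	T cell, TCR	immune_signaling	-	17
ENSG00000171862.5	PTEN	Phosphatase and tensin homolog	T cell, TCR	immune_signaling	-	3
ENSG00000105287.8	PRKD2	Protein kinase D2	T cell, TCR	immune_signaling	-	7
ENSG00000110852.4	CLEC2B	C-type lectin domain family 2 member B	-	adaptive_immunity	-	3
ENSG00000182179.6	UBA7	Ubiquitin like modifier activating enzyme 7	-	adaptive_immunity	rs11715915,rs6997,rs9814873	7
ENSG00000163599.10	CTLA4	Cytotoxic T-lymphocyte associated protein 4	-	adaptive_immunity	-	7
ENSG00000150637.4	CD226	CD226 molecule	-	adaptive_immunity	-	8
ENSG00000136153.15	LMO7	LIM domain 7	-	adaptive_immunity	-	13
ENSG00000172575.7	RASGRP1	RAS guanyl releasing protein 1	-	adaptive_immunity	-	14
ENSG00000164068.11	RNF123	Ring finger protein 123	-	adaptive_immunity	rs11715915,rs6997,rs9814873	19
ENSG00000224389.4	C4B	Complement C4B (Chido blood group)	Complement factor	adaptive_immunity	rs3129716	27
ENSG00000244731.3	C4A	Complement C4A (Rodgers blood group)	Complement factor	adaptive_immunity	rs3129716	27
ENSG00000187796.9	CARD9	Caspase recruitment domain family member 9	-	innate_immunity	-	7
ENSG00000164062.8	APEH	Acylaminoacyl-peptide hydrolase	Acylpeptide hydrolase	innate_immunity	rs11715915,rs6997,rs9814873	18
ENSG00000167914.6	GSDMA	Gasdermin A	Bactericidal activity	innate_immunity	-	16
ENSG00000172057.5	ORMDL3	ORMDL sphingolipid biosynthesis regulator 3	Protein binding	innate_immunity	-	10
ENSG00000204540.6	PSORS1C1	Psoriasis susceptibility 1 candidate 1	Inflammation, Psoriasis	innate_immunity	rs886424,rs1264361	11
ENSG00000185010.9	F8	Coagulation factor VIII	Blood coagulation	other_immune	-	9
ENSG00000176046.7	NUPR1	Nuclear protein 1, transcriptional regulator	Transcription factor	other_immune	rs4788084,rs62031562,rs743590,rs762633	17
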