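rsid	db_source	chrom	pos	n_eqtl_genes	n_lncrnas	tf_motifs
rs886424	GWAS	chr6	30782002	11	2	-
rs3129716	LDlink	chr6	32657436	14	1	-
rs1264361	LDlink	chr6	30777498	11	0	-
rs9268606	LDlink	chr6	32400070	7	0	-
rs1049053	LDlink	chr6	32634405	0	0	-
rs9274626	LDlink	chr6	32636040	0	0	-
rs9388486	LDlink	chr6	126661154	0	1	-
rs3024493	LDlink	chr1	206943968	0	0	-
rs3024505	GWAS	chr1	206939904	0	0	-
rs478222	GWAS	chr2	25301755	3	0	-
rs11715915	LDlink	chr3	49455330	9	0	-
rs6997	LDlink	chr3	49453834	8	0	-
rs9814873	LDlink	chr3	49454112	9	0	-
rs7725052	GWAS	chr5	40487270	0	0	-
rs7731626	GWAS	chr5	55444683	0	0	-
rs68037604	LDlink	chr11	2212487	0	1	-
rs10876870	LDlink	chr12	56478002	3	0	-
rs4759229	LDlink	chr12	56474480	3	0	-
rs4788084	GWAS	chr16	28539848	17	0	EBF1
rs62031562	LDlink	chr16	28609329	18	0	-
rs743590	LDlink	chr16	28608230	18	0	-
rs762633	LDlink	chr16	28608341	18	0	-
rs12919083	LDlink	chr16	11188930	0	0	-
rs7203793	LDlink	chr16	11182134	0	0	-
rs3746923	LDlink	chr21	43826344	0	0	-
rs229544	LDlink	chr22	37593080	1	0	MAX,USF1
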