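rsid	gene_symbol	cluster	direction	n_tissues
rs4788084	SULT1A2	1	up	34
rs4788084	SULT1A1	1	down	12
rs4788084	IL27	1	up	2
rs4788084	NPIPB6	2	mixed	2
rs4788084	NPIPB7	2	down	16
rs4788084	NPIPB9	2	down	2
rs4788084	ATP2A1-AS1	2	down	1
rs4788084	AC145285.5	2	up	5
rs4788084	AC138894.3	2	down	4
rs4788084	TUFM	3	up	19
rs4788084	EIF3C	3	up	2
rs4788084	CDC37P1	3	up	19
rs4788084	SH2B1	3	up	1
rs4788084	NUPR1	3	up	1
rs4788084	SPNS1	3	up	1
rs4788084	AC145285.2	3	up	1
rs4788084	SBK1	3	up	1
rs62031562	SULT1A2	1	up	34
rs62031562	SULT1A1	1	down	12
rs62031562	IL27	1	up	2
rs62031562	NPIPB6	2	mixed	2
rs62031562	NPIPB7	2	down	16
rs62031562	NPIPB9	2	down	2
rs62031562	ATP2A1-AS1	2	down	1
rs62031562	AC145285.5	2	up	5
rs62031562	AC138894.3	2	down	4
rs62031562	TUFM	3	up	19
rs62031562	EIF3C	3	up	2
rs62031562	CDC37P1	3	up	19
rs62031562	SH2B1	3	up	1
rs62031562	NUPR1	3	up	1
rs62031562	SPNS1	3	up	1
rs62031562	AC145285.2	3	up	1
rs62031562	SGF29	3	down	1
rs62031562	RABEP2	3	up	1
rs743590	SULT1A2	1	up	34
rs743590	SULT1A1	1	down	12
rs743590	IL27	1	up	2
rs743590	NPIPB6	2	mixed	2
rs743590	NPIPB7	2	down	16
rs743590	NPIPB9	2	down	2
rs743590	ATP2A1-AS1	2	down	1
rs743590	AC145285.5	2	up	5
rs743590	AC138894.3	2	down	4
rs743590	TUFM	3	up	19
rs743590	EIF3C	3	up	2
rs743590	CDC37P1	3	up	19
rs743590	SH2B1	3	up	1
rs743590	NUPR1	3	up	1
rs743590	SPNS1	3	up	1
rs743590	AC145285.2	3	up	1
rs743590	SGF29	3	down	1
rs743590	RABEP2	3	up	1
rs762633	SULT1A2	1	up	34
rs762633	SULT1A1	1	down	12
rs762633	IL27	1	up	2
rs762633	NPIPB6	2	mixed	2
rs762633	NPIPB7	2	down	16
rs762633	NPIPB9	2	down	2
rs762633	ATP2A1-AS1	2	down	1
rs762633	AC145285.5	2	up	5
rs762633	AC138894.3	2	down	4
rs762633	TUFM	3	up	19
rs762633	EIF3C	3	up	2
rs762633	CDC37P1	3	up	19
rs762633	SH2B1	3	up	1
rs762633	NUPR1	3	up	1
rs762633	SPNS1	3	up	1
rs762633	AC145285.2	3	up	1
rs762633	SGF29	3	down	1
rs762633	RABEP2	3	up	1
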