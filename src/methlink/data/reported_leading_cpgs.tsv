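cpg_id	chrom	gene
cg15325070	1
cg25189904	1	GNG12
cg14179389	1	GFI1
cg04749740	2
cg06635952	2	ANXA4
cg11025974	2	CACNB4
cg14157435	2	NRP2
cg05783384	2
cg05204104	2	ARL4C
cg00174179	3	RHOA
cg16449012	4	FAM184B
cg05575921	5	AHRR
cg21253335	5
cg01952185	5
cg05634495	6
cg00794911	6
cg25879142	7
cg20117519	7
cg19089201	7	MYO1G
cg04598670	7
cg25949550	7	CNTNAP2
cg11207515	7	CNTNAP2
cg15578140	7	MIR548F3
cg17199018	8	ZNF395
cg14563637	9
cg14540913	9	PRRX2
cg13822849	9	OLFM1
cg11813497	10	FRMD4A
cg05697249	11	C11orf52
cg18493761	11
cg05549655	15	CYP1A1
cg13834112	15
cg00253658	16
cg04358214	16	C16orf70
cg12984635	19	ETHE1
cg06758350	21	RUNX1
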