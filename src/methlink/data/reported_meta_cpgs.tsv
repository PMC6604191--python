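cpg_id	chrom	pos	gene	beta	se	pval
cg04180046	7	45002736	MYO1G	0.045	0.003	2.60E-54
cg12803068	7	45002919	MYO1G	0.077	0.005	5.70E-45
cg22132788	7	45002486	MYO1G	0.045	0.003	6.80E-38
cg19089201	7	45002287	MYO1G	0.035	0.003	1.20E-31
cg05549655	15	75019143	CYP1A1	0.010	0.001	1.00E-28
cg25949550	7	145814306	CNTNAP2	-0.007	0.001	5.40E-27
cg18493761	11	125386885		0.037	0.004	7.30E-21
cg15507334	10	14372913	FRMD4A	0.024	0.003	1.80E-20
cg14179389	1	92947961	GFI1	-0.028	0.003	5.00E-20
cg00253658	16	54210496		0.037	0.004	3.40E-19
cg17924476	5	323794	AHRR	0.024	0.003	4.40E-19
cg13570656	15	75019196	CYP1A1	0.036	0.004	7.40E-19
cg11813497	10	14372879	FRMD4A	0.026	0.003	9.30E-19
cg22549041	15	75019251	CYP1A1	0.041	0.005	2.60E-18
cg05575921	5	373378	AHRR	-0.019	0.002	3.50E-18
cg12101586	15	75019203	CYP1A1	0.032	0.004	1.20E-17
cg18092474	15	75019302	CYP1A1	0.036	0.004	1.50E-17
cg11924019	15	75019283	CYP1A1	0.013	0.002	2.90E-16
cg25464840	10	14372910	FRMD4A	0.019	0.002	9.30E-16
cg00213123	15	75019070	CYP1A1	0.012	0.002	7.80E-15
cg11207515	7	146904205	CNTNAP2	-0.023	0.003	1.00E-13
cg14157435	2	206628692	NRP2	-0.046	0.006	1.10E-13
cg05348875	2	206628625	NRP2	-0.040	0.006	7.60E-13
cg01952185	5	134813213		0.019	0.003	3.30E-12
cg22308949	2	206628553	NRP2	-0.022	0.003	4.40E-12
cg05204104	2	235403141	ARL4C	0.017	0.003	4.80E-12
cg11641006	2	235213874		0.017	0.003	7.90E-12
cg09935388	1	92947588	GFI1	-0.029	0.004	1.10E-11
cg05697249	11	111789693	C11orf52	0.015	0.002	1.30E-11
cg21161138	5	399360	AHRR	-0.013	0.002	1.50E-11
cg26681628	16	54210550		0.018	0.003	1.80E-11
cg11025974	2	152830521	CACNB4	0.016	0.002	9.10E-11
cg15016771	2	235403218	ARL4C	0.008	0.001	1.00E-10
cg11429115	5	134813329		0.014	0.002	1.30E-10
cg25189904	1	68299493	GNG12	-0.020	0.003	1.30E-10
cg06758350	21	36259460	RUNX1	0.030	0.005	1.70E-10
cg17852385	15	75019188	CYP1A1	0.010	0.002	2.60E-10
cg01664727	21	36258423	RUNX1	0.027	0.004	2.60E-10
cg20344448	10	14372431	FRMD4A	0.014	0.002	2.80E-10
cg00794911	6	166260532		-0.012	0.002	5.20E-10
cg22698744	21	36263808	RUNX1	0.023	0.004	7.30E-10
cg03142697	21	36258497	RUNX1	0.016	0.003	8.10E-10
cg14563637	9	98931801		0.016	0.003	1.20E-09
cg15091747	21	36262896	RUNX1	0.014	0.002	1.20E-09
cg12984635	19	44032076	ETHE1	0.015	0.002	2.20E-09
cg01825213	9	98979965		0.019	0.003	2.50E-09
cg12477880	21	36259241	RUNX1	0.038	0.006	2.80E-09
cg17199018	8	28206278	ZNF395	-0.017	0.003	3.90E-09
cg00174179	3	49450293	RHOA;TCTA	-0.006	0.001	7.00E-09
cg15578140	7	147718109	MIR548F3;CNTNAP2	0.011	0.002	7.50E-09
cg14540913	9	132458514	PRRX2	0.013	0.002	7.60E-09
cg18132363	6	166260572		-0.019	0.003	7.60E-09
cg21253335	5	87835928		0.017	0.003	1.30E-08
cg25879142	7	4671391		0.018	0.003	1.80E-08
cg11845417	11	111789613	C11orf52	0.011	0.002	2.40E-08
cg20117519	7	8429907		0.022	0.004	2.40E-08
cg05783384	2	218843735		0.021	0.004	2.60E-08
cg13822849	9	137999757	OLFM1	0.007	0.001	2.90E-08
cg16449012	4	17781880	FAM184B	0.014	0.002	3.10E-08
cg05634495	6	122364658		0.016	0.003	3.10E-08
cg08644678	4	17711202	FAM184B	0.009	0.002	3.10E-08
cg13834112	15	90361639		0.013	0.002	3.60E-08
cg06635952	2	70025869	ANXA4	0.011	0.002	5.50E-08
cg14485097	7	4671479		0.016	0.003	7.40E-08
cg04598670	7	68697651		-0.019	0.003	8.30E-08
cg03252786	11	125106056	PKNOX2	0.006	0.001	8.70E-08
cg04749740	2	65935124		0.015	0.003	9.20E-08
cg15325070	1	2792704		0.014	0.003	9.20E-08
cg04358214	16	67143304	C16orf70	0.022	0.004	9.60E-08
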