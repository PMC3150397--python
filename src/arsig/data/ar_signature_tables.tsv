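genbank_id	symbol	cytoband	cell_line	treatment	direction	mean_2log_ratio	sam_q
NM_018674	ACCN4	2q35	PC346C	R1881	up	0.7	0.000
NM_004457	ACSL3	2q34-q35	PC346Flu1	R1881	up	2.0	0.000
NM_014109	ATAD2	8q24.13	PC346Flu1	R1881	up	0.8	0.000
AK027213	BBS10	12q21.2	PC346Flu1	R1881	up	0.8	0.000
NM_020235	BBX	3q13.1	PC346Flu1	R1881	up	0.8	0.007
AK024850	C2orf31	2q34	PC346Flu1	R1881	up	1.3	0.000
NM_006079	CITED2	6q23.3	PC346Flu1	R1881	up	1.0	0.000
AK026498	CYP2U1	4q25	PC346Flu1	R1881	up	1.5	0.000
NM_012062	DNM1L	12p11.21	PC346Flu1	R1881	up	1.4	0.000
NM_018456	EAF2	3q13.33	PC346Flu1	R1881	up	2.3	0.000
AK026517	EHF	11p12	PC346Flu1	R1881	up	0.6	0.000
AK022827	EIF2C3	1p34.3	PC346C	R1881	up	0.6	0.056
AK022827	EIF2C3	1p34.3	PC346Flu1	R1881	up	1.0	0.000
NM_012081	ELL2	5q15	PC346Flu1	R1881	up	1.8	0.000
NM_012081	ELL2	5q15	PC346Flu2	R1881	up	1.0	1.093
AF111849	ELOVL5	6p21.1-p12.1	PC346Flu1	R1881	up	1.5	0.000
AB020637	ENDOD1	11q21	PC346Flu1	R1881	up	1.3	0.000
AB020637	ENDOD1	11q21	PC346Flu2	R1881	up	1.1	1.093
NM_019018	FAM105A	5p15.2	PC346Flu1	R1881	up	1.0	0.000
AK024648	FAM107B	10p13	PC346Flu1	R1881	up	0.8	0.007
AL137343	FAM84A	2p24.3	PC346Flu1	R1881	up	1.1	0.000
NM_004117	FKBP5	6p21.3-21.2	PC346C	R1881	up	1.9	0.000
NM_004117	FKBP5	6p21.3-21.2	PC346Flu1	R1881	up	4.2	0.000
NM_004117	FKBP5	6p21.3-21.2	PC346Flu2	R1881	up	1.7	1.093
AK024715	FLJ21062	7q21.13	PC346Flu1	R1881	up	1.4	0.000
NM_020474	GALNT1	18q12.1	PC346Flu1	R1881	up	0.8	0.000
NM_005271	GLUD1	10q23.3	PC346Flu1	R1881	up	1.1	0.000
NM_002069	GNAI1	7q21	PC346Flu1	R1881	up	0.9	0.000
AB042410	GPR88	1p21.3	PC346C	R1881	up	1.4	0.000
AB042410	GPR88	1p21.3	PC346Flu1	R1881	up	3.0	0.000
AB042410	GPR88	1p21.3	PC346Flu2	R1881	up	2.6	0.125
NM_001530	HIF1A	14q21-q24	PC346Flu1	R1881	up	1.2	0.000
NM_003543	HIST1H4H	6p21.3	PC346Flu1	R1881	up	1.7	0.000
M60721	HLX	1q41-q42.1	PC346Flu1	R1881	up	0.7	0.000
M60721	HLX	1q41-q42.1	PC346Flu2	R1881	up	0.6	1.093
NM_014642	IQCB1	3q13.33	PC346Flu1	R1881	up	0.8	0.139
NM_002241	KCNJ10	1q22-q23	PC346C	R1881	up	0.7	0.056
AL137384	KIAA1109	4q27	PC346C	R1881	up	0.6	0.027
NM_001206	KLF9	9q13	PC346Flu1	R1881	up	0.8	0.000
AF188747	KLK2	19q13.41	PC346C	R1881	up	0.8	0.000
AF188747	KLK2	19q13.41	PC346Flu1	R1881	up	1.1	0.000
AF188747	KLK2	19q13.41	PC346Flu2	R1881	up	1.0	1.093
AK026375	LOC93622	4p16.1	PC346Flu1	R1881	up	1.0	0.000
NM_005461	MAFB	20q11.2-q13.1	PC346Flu1	R1881	up	1.1	0.000
NM_003010	MAP2K4	17p11.2	PC346Flu1	R1881	up	0.8	0.000
AB050049	MCCC2	5q12-q13	PC346Flu1	R1881	up	1.1	0.000
AK021627	MORC4	Xq22.3	PC346Flu1	R1881	up	1.2	0.000
AF142409	MS4A6A	11q12.1	PC346Flu1	R1881	up	0.8	0.450
NM_005956	MTHFD1	14q24	PC346C	R1881	up	0.6	0.000
NM_016498	MTP18	22q	PC346C	R1881	up	0.6	0.000
NM_000662	NAT1	8p23.1-p21.3	PC346Flu1	R1881	up	1.7	0.000
AF039944	NDRG1	8q24.3	PC346Flu1	R1881	up	1.6	0.000
NM_006096	NDRG1	8q24.3	PC346Flu1	R1881	up	2.6	0.000
AK026383	NDRG1	8q24.3	PC346Flu1	R1881	up	2.1	0.000
NM_005596	NFIB	9p24.1	PC346Flu1	R1881	up	0.8	0.077
NM_020529	NFKBIA	14q13	PC346C	R1881	up	0.7	0.000
NM_020529	NFKBIA	14q13	PC346Flu1	R1881	up	2.4	0.000
NM_020529	NFKBIA	14q13	PC346Flu2	R1881	up	0.7	1.093
NM_016590	PART1	5q12.1	PC346Flu1	R1881	up	1.5	0.000
NM_006810	PDIA5	3q21.1	PC346C	R1881	up	0.5	0.000
NM_006810	PDIA5	3q21.1	PC346Flu1	R1881	up	1.4	0.000
NM_016166	PIAS1	15q	PC346Flu1	R1881	up	1.3	0.000
AF070670	PPM1A	14q23.1	PC346Flu1	R1881	up	0.7	0.000
NM_004156	PPP2CB	8p12-p11.2	PC346Flu1	R1881	up	0.9	0.000
NM_002923	RGS2	1q31	PC346Flu2	R1881	up	0.7	0.000
D16875	RHOB	2p24	PC346Flu1	R1881	up	1.6	0.000
AK001478	RHOU	1q42.11-q42.3	PC346C	R1881	up	0.8	0.000
AK001478	RHOU	1q42.11-q42.3	PC346Flu1	R1881	up	2.3	0.000
AK001478	RHOU	1q42.11-q42.3	PC346Flu2	R1881	up	1.0	0.000
AB051826	RHOU	1q42.11-q42.3	PC346Flu1	R1881	up	2.5	0.000
NM_005627	SGK1	6q23	PC346Flu1	R1881	up	0.9	0.000
AB040914	SHROOM3	4q21.1	PC346Flu1	R1881	up	1.0	0.012
NM_004595	SMS	Xp22.1	PC346Flu1	R1881	up	1.1	0.000
NM_003082	SNAPC1	14q22	PC346Flu1	R1881	up	0.6	0.166
NM_003104	SORD	15q15.3	PC346Flu1	R1881	up	1.2	0.000
NM_012449	STEAP1	7q21	PC346C	R1881	up	0.8	0.000
NM_012449	STEAP1	7q21	PC346Flu1	R1881	up	1.7	0.000
NM_012449	STEAP1	7q21	PC346Flu2	R1881	up	1.0	1.093
AK026813	STEAP2	7q21	PC346Flu1	R1881	up	1.1	0.000
AK026813	STEAP2	7q21	PC346Flu2	R1881	up	0.7	0.000
NM_005656	TMPRSS2	21q22.3	PC346C	R1881	up	0.6	0.117
NM_005079	TPD52	8q21	PC346Flu1	R1881	up	1.2	0.000
NM_005079	TPD52	8q21	PC346Flu2	R1881	up	0.7	0.208
AF294628	TWSG1	18p11.3	PC346Flu1	R1881	up	1.0	0.000
NM_003115	UAP1	1q23.3	PC346Flu1	R1881	up	1.0	0.000
NM_003359	UGDH	4p15.1	PC346C	R1881	up	0.6	0.098
NM_003359	UGDH	4p15.1	PC346Flu1	R1881	up	1.9	0.000
AK001647	USP40	2q37.1	PC346C	R1881	up	0.7	0.000
AB020676	WWC1	5q34	PC346Flu1	R1881	up	0.7	0.000
AK022814	ZBTB10	8q13-q21.1	PC346Flu1	R1881	up	1.3	0.000
AK022814	ZBTB10	8q13-q21.1	PC346Flu2	R1881	up	0.5	1.093
NM_006006	ZBTB16	11q23.1	PC346C	R1881	up	0.9	0.000
NM_006006	ZBTB16	11q23.1	PC346Flu1	R1881	up	1.6	0.000
NM_006006	ZBTB16	11q23.1	PC346Flu2	R1881	up	1.5	1.093
AF025771	ZNF189	9q22-q31	PC346Flu1	R1881	up	1.5	0.000
AL157445			PC346Flu1	R1881	up	1.0	0.007
D17210			PC346Flu1	R1881	up	1.0	0.000
NM_005688	ABCC5	3q27	PC346Flu1	R1881	down	-0.7	0.282
AK026288	ATHL1	11p15.5	PC346Flu1	R1881	down	-1.0	0.008
NM_012342	BAMBI	10p12.3-p11.2	PC346Flu1	R1881	down	-1.0	0.000
NM_001197	BIK	22q13.31	PC346Flu1	R1881	down	-0.8	0.112
AF075110	C14orf4	14q24.3	PC346Flu1	R1881	down	-1.3	0.000
NM_017766	CASZ1	1p36.22	PC346Flu1	R1881	down	-1.0	0.112
NM_001305	CLDN4	7q11.23	PC346Flu1	R1881	down	-0.6	0.282
AK024378	FAM131A	3q27.1	PC346Flu1	R1881	down	-0.7	0.052
NM_004480	FUT8	14q24.3	PC346Flu1	R1881	down	-1.0	0.316
NM_002165	ID1	20q11	PC346Flu1	R1881	down	-0.8	0.018
NM_002165	ID1	20q11	PC346Flu2	R1881	down	-1.1	1.087
X69111	ID3	1p36.13-p36.12	PC346Flu1	R1881	down	-1.3	0.000
NM_006769	LMO4	1p22.3	PC346Flu1	R1881	down	-0.8	0.000
NM_017572	MKNK2	19p13.3	PC346Flu1	R1881	down	-0.7	0.088
NM_005377	MYCL2	Xq22-q23	PC346C	R1881	down	-1.0	0.116
NM_006312	NCOR2	12q24	PC346Flu1	R1881	down	-0.6	0.052
U90907	PIK3R3	1p34.1	PC346Flu1	R1881	down	-1.0	0.008
AF113132	PSAT1	9q21.2	PC346Flu1	R1881	down	-0.8	0.000
NM_004577	PSPH	7p15.2-p15.1	PC346Flu1	R1881	down	-0.9	0.041
NM_015923	SLC3A2	11q13	PC346Flu1	R1881	down	-0.6	0.263
NM_003943	STBD1	4q24-q25	PC346Flu1	R1881	down	-0.8	0.022
NM_003714	STC2	5q35.1	PC346Flu1	R1881	down	-0.6	0.088
AK000401	TANC1	2q24.2	PC346Flu2	R1881	down	-0.7	1.087
AL133074	TP53INP1	8q22	PC346Flu1	R1881	down	-1.3	0.000
NM_003287	TPD52L1	6q22-q23	PC346Flu1	R1881	down	-0.7	0.402
AF205437	TRIB1	8q24.13	PC346Flu1	R1881	down	-1.6	0.000
U55055			PC346Flu2	R1881	down	-1.0	1.087
NM_018588			PC346C	R1881	down	-0.6	0.194
NM_018588			PC346Flu1	R1881	down	-0.6	0.422
AK022971			PC346Flu1	R1881	down	-0.7	0.450
AK022971			PC346Flu2	R1881	down	-0.7	1.087
AB020637	ENDOD1	11q21	PC346Flu2	OHF	up	0.6	0.158
NM_004117	FKBP5	6p21.3-21.2	PC346Flu2	OHF	up	0.7	0.226
AB042410	GPR88	1p21.3	PC346Flu2	OHF	up	1.9	0.000
AK025585	PARS2	1p32.2	PC346Flu2	OHF	up	0.8	0.296
NM_019091	PLEKHA3	2q31.2	PC346Flu2	OHF	up	0.7	0.158
NM_002923	RGS2	1q31	PC346Flu2	OHF	up	0.6	0.000
AK026813	STEAP2	7q21	PC346Flu2	OHF	up	0.6	0.118
D17099			PC346Flu2	OHF	up	0.9	0.926
NM_014805	EPM2AIP1	3p22.1	PC346Flu2	OHF	down	-0.8	0.301
NM_006854	KDELR2	7p22.1	PC346C	OHF	down	-0.8	0.118
AB028451	NCOR1	17p11.2	PC346Flu2	OHF	down	-1.2	0.301
AB046842	PPP4R4	14q32.12-q32.13	PC346Flu2	OHF	down	-0.7	0.301
NM_001269	RCC1	1p36.1	PC346Flu2	OHF	down	-0.7	0.301
NM_000370	TTPA	8q13.1-q13.3	PC346Flu2	OHF	down	-0.9	0.301
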