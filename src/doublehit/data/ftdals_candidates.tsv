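# Published FTD-ALS double-hit candidate list: 30 risk SNPs over 26 genes that
# are both GWAS-associated (P < 0.05, exonic/splicing, nonsynonymous/stopgain,
# CADD > 15) and differentially methylated in blood (probe P_BH < 0.05).
# Genomic coordinates are SYNTHETIC placeholders (the published table prints
# none); they are constructed so that no SNP falls inside a probe CpG site,
# matching the published observation of zero SNP/probe colocalizations.
# Rows with a non-empty distractor_reason are SYNTHETIC negative controls,
# each violating exactly one candidate-filter criterion; they are not part of
# the published list.
gene_symbol	chromosome	strand	rsid	snp_position	gwas_p	func_class	consequence	cadd	min_p_for_gene	probe_id	probe_position	dmp_p_bh	island_relation	t_stat	degree	pathway_overlap	validated	distractor_reason
DLG1	chr3	-	rs74674649	1010000	6.01e-04	exonic	nonsynonymous	28.2	6.01e-04	cg12594803	1010500	0.0288	open_sea	-7.04	6	yes	yes
KIAA1147	chr7	-	rs201876806	1020000	9.13e-04	exonic	nonsynonymous	23.4	9.13e-04	cg24662653	1020500	0.0029	Island	-6.51	2		yes
GGA1	chr22	+	rs143909159	1030000	2.91e-03	exonic	nonsynonymous	34	2.91e-03	cg21268578	1030500	0.028	open_sea	-7.16	21
IGHMBP2	chr11	+	rs201692151	1040000	4.00e-03	exonic	stopgain	22.8	4.00e-03	cg26065952	1040500	0.0231	N_Shore	-5.7	31		yes
ASPM	chr1	-	rs150125249	1050000	5.78e-03	exonic	nonsynonymous	34	5.78e-03	cg11336294	1050500	0.0273	open_sea	-5.59		yes
PRSS36	chr16	-	rs145749002	1060000	6.04e-03	exonic	nonsynonymous	33	6.04e-03	cg14301190	1060500	0.0049	Island	-6.68	1
CNKSR1	chr1	+	rs144396219	1070000	8.32e-03	exonic	nonsynonymous	27.7	8.32e-03	cg09890400	1070500	0.0196	open_sea	-8.83	11	yes
UBTD2	chr5	-	rs17074452	1080000	9.54e-03	exonic	nonsynonymous	18.33	9.54e-03	ch.5.3268483F	1080500	0.0049	open_sea	-5.84	12		yes
GGA1	chr22	+	rs138525343	1090000	9.76e-03	exonic	nonsynonymous	26.6	2.91e-03	cg21268578	1030500	0.028	open_sea	-7.16	21
IGHMBP2	chr11	+	rs145226920	1100000	0.01001	exonic	nonsynonymous	35	4.00e-03	cg26065952	1040500	0.0231	N_Shore	-5.7	31		yes
FAH	chr15	+	rs144234072	1110000	0.01066	exonic	nonsynonymous	27.3	0.01066	cg06856840	1110500	0.0165	open_sea	-6.95	2	yes
NEDD9	chr6	-	rs34044517	1120000	0.01629	exonic	nonsynonymous	23.6	5.85e-03	cg05917225	1120500	0.0092	open_sea	-5.79	2
BPHL	chr6	+	rs2231365	1130000	0.01671	splicing	nonsynonymous	24.1	0.01671	cg22799902	1130500	0.0062	Island	-6.43	2
ACTN3	chr11	+	rs201576110	1140000	0.02133	exonic	nonsynonymous	32	0.02133	cg25117505	1140500	6.39e-06	Island	-8.39
WDR66	chr12	+	rs77422261	1150000	0.02336	exonic	nonsynonymous	29.7	0.02336	cg21016266	1150500	0.0133	Island	-4.89	3
IQSEC1	chr3	-	rs144790333	1160000	0.02763	exonic	nonsynonymous	23	0.02763	cg02559896	1160500	0.0067	Island	-5.14	16	yes
DLG1	chr3	-	rs141544348	1170000	0.03024	exonic	nonsynonymous	35	6.01e-04	cg12594803	1010500	0.0288	open_sea	-7.04	6	yes	yes
DUOX1	chr15	+	rs143304688	1180000	0.03047	exonic	nonsynonymous	44	0.03047	cg10496082	1180500	2.00e-04	Island	-6.61	4	yes
PCDHA3	chr5	+	rs146951816	1190000	0.0354	exonic	nonsynonymous	15.16	0.0354	cg02357321	1190500	0.0335	N_Shore	-6.43
C6orf70	chr6	+	rs140632188	1200000	0.04056	exonic	nonsynonymous	23	0.04056	cg22807378	1200500	0.0121	Island	-7.15	1
CLRN2	chr4	+	rs201124485	1210000	0.04711	exonic	nonsynonymous	20.6	0.04711	cg16760587	1210500	0.0011	S_Shelf	-6.06
COL15A1	chr9	+	rs199906142	1220000	3.62e-03	exonic	nonsynonymous	23.1	3.62e-03	cg18115656	1220500	0.0366	Island	5.37	0	yes
TNRC18	chr7	-	rs112785272	1230000	6.27e-03	exonic	nonsynonymous	19.2	6.27e-03	cg10546562	1230500	0.0101	N_Shore	5.91	28	yes
SLC26A7	chr8	+	rs200788056	1240000	9.04e-03	exonic	nonsynonymous	23.3	9.04e-03	cg25481252	1240500	0.0026	open_sea	7.38
PCNX	chr14	+	rs200261097	1250000	0.01309	exonic	nonsynonymous	32	0.01309	cg10066683	1250500	0.0422	open_sea	5.34	31	yes	yes
WDR35	chr2	-	rs148436608	1260000	0.02293	exonic	nonsynonymous	16.34	0.02293	cg13734338	1260500	0.028	open_sea	6.0	0		yes
MEGF6	chr1	-	rs61910697	1270000	0.03109	exonic	nonsynonymous	19.86	0.03109	cg04391135	1270500	0.0035	Island	6.21	0
PRR5-ARHGAP8	chr22	+	rs55849456	1280000	0.03933	exonic	nonsynonymous	24.6	0.03933	cg06647930	1280500	0.0442	S_Shelf	4.26		yes
PRR5-ARHGAP8	chr22	+	rs16992915	1290000	0.04662	exonic	nonsynonymous	19.38	0.03933	cg06647930	1280500	0.0442	S_Shelf	4.26		yes
ESYT2	chr7	-	rs2305475	1300000	0.04728	exonic	nonsynonymous	23	0.04728	cg19584649	1300500	9.36e-05	open_sea	6.66	15	yes
DSTGENE1	chr1	+	rs900000001	2010000	0.06	exonic	nonsynonymous	30	0.06	cgdst00001	2010500	0.001	Island	-5.0				gwas_p_above_threshold
DSTGENE2	chr2	+	rs900000002	2020000	0.01	intronic	none	22	0.01	cgdst00002	2020500	0.001	Island	-5.0				func_class_intronic
DSTGENE3	chr3	+	rs900000003	2030000	0.01	exonic	synonymous	30	0.01	cgdst00003	2030500	0.001	Island	-5.0				consequence_synonymous
DSTGENE4	chr4	+	rs900000004	2040000	0.01	exonic	nonsynonymous	14	0.01	cgdst00004	2040500	0.001	Island	-5.0				cadd_below_threshold
DSTGENE5	chr5	+	rs900000005	2050000	0.01	exonic	nonsynonymous	25	0.01	cgdst00005	2050500	0.2	Island	-5.0				dmp_not_significant
DSTGENE6	chr6	+	rs900000006	2060000	0.01	exonic	nonsynonymous	15	0.01	cgdst00006	2060500	0.001	Island	-5.0				cadd_at_boundary
DSTGENE7	chr7	+	rs900000007	2070000	0.05	exonic	nonsynonymous	30	0.05	cgdst00007	2070500	0.001	Island	-5.0				gwas_p_at_boundary
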