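locus_id	chrom	start	end	length	gene_5p	dist_5p	gene_3p	dist_3p	ad_reads	amc_reads	ratio_printed	p_printed
RP5-857K21.4	1	633888	634164	277	RP5-857K21.3	36389	RP5-857K21.4	0	515	1360	0.38	0.0001
SKI	1	2281959	2282363	405	SKI	0	MORN1	38889	1396	1967	0.71	0.0001
SCARNA2	1	109100211	109100485	275	SCARNA2	0	RP5-1065J22.4	3049	131	98	1.34	0.05
HNRNPU	1	244863775	244864066	292	RP11-11N7.5	8277	HNRNPU	0	509	653	0.78	0.004
LINC00486	2	32916221	32916538	318	LINC00486	0	AL121656.5	10588	17	5	3.40	0.02
AC073283.4	2	47335292	47335571	280	CALM2	158690	AC073283.4	0	2728	2093	1.30	0.0002
KIF5C	2	148961908	148962183	276	KIF5C	0	LYPD6B	75923	3055	1856	1.65	0.0001
CERKL	2	181678574	181678849	276	ITGA4	142386	CERKL	0	107	60	1.78	0.001
NCL	2	231460607	231460888	282	AC017104.2	7453	NCL	0	41	27	1.52	NS
ATG16L1/SCARNA5	2	233275721	233275994	274	ATG16L1	0	SCARNA5	0	400	206	1.94	0.0001
KIF1A	2	240713854	240714163	310	RP11-118M12.2	12168	KIF1A	0	2806	4988	0.56	0.0001
KPNA4	3	160514943	160515216	274	RNU7-136P	42526	KPNA4	0	536	232	2.31	0.0001
HIST1H4E	6	26204696	26204971	276	HIST1H4E	0	HIST1H2BG	11094	164	304	0.54	0.0001
GRM4	6	34071883	34072162	280	MIR1275	71831	GRM4	0	10689	5521	1.94	0.0001
RN7SK	6	52995648	52995925	278	RN7SK	0	ICK	5353	32569	12138	2.68	0.0001
PNISR	6	99408034	99408309	276	COQ3	13829	PNISR	0	206	135	1.53	0.001
ACTB	7	5529123	5529444	322	MIR589	33205	ACTB	0	1210	1719	0.70	0.0001
HNRNPA2B1	7	26200464	26200741	278	CTB-119C2.1	25518	HNRNPA2B1	0	168	99	1.70	0.0002
LINC00599	8	9903986	9904242	257	MIR597	162217	LINC00599	0	1667	1113	1.50	0.0001
CLU	8	27604977	27605252	276	GULOP	15903	CLU	0	156	105	1.49	0.005
RMRP_1	9	35657748	35658022	275	SIT1	6797	RMRP_1	0	472	184	2.57	0.0001
MGEA5	10	101799051	101799385	335	NPM3	15637	MGEA5	0	683	432	1.58	0.0001
TRIM44	11	35663281	35663611	331	TRIM44	0	KRT18P14	196637	1147	592	1.94	0.0001
WDR74	11	62841562	62841839	278	RP11-727F15.9	7518	WDR74	0	304	149	2.04	0.0001
MALAT1_1	11	65502716	65503064	349	AP000769.7	4310	MALAT1_1	0	30539	16494	1.85	0.0001
CRYAB	11	111911504	111911780	277	RPL37AP8	22029	CRYAB	0	228	216	1.06	NS
HSPA8	11	123061064	123061339	276	RPL31P47	9662	HSPA8	0	871	1512	0.58	0.0001
ATP2A2	12	110281619	110281909	291	ATP2A2	0	RN7SL769P	78542	433	225	1.92	0.0001
ZC3H13	13	45975357	45975649	293	AL445232.1	60203	ZC3H13	0	372	240	1.55	0.0001
RPPH1	14	20343094	20343370	277	SNORD126	16567	RPPH1	0	2313	634	3.65	0.0001
PABPN1	14	23321579	23321860	282	PABPN1	0	SLC22A17	24445	341	261	1.31	0.01
RPS29	14	49586595	49586871	277	RNA5SP384	33846	RPS29	0	22800	4958	4.60	0.0001
Metazoa_SRP_138	14	49853648	49853923	276	RNU6-539P	13820	Metazoa_SRP_138	0	24010	7554	3.18	0.0001
HSP90AA1	14	102084750	102085033	284	RN7SL472P	7277	HSP90AA1	0	186	94	1.98	0.0001
PITPNM3	17	6452910	6453209	300	FAM64A	1440	PITPNM3	0	671	520	1.29	0.004
SNORD3A	17	19187969	19188246	278	KYNUP1	18300	SNORD3A	0	342	99	3.45	0.0001
GFAP	17	44911190	44911459	270	AC015936.3	6643	GFAP	0	7051	8989	0.78	0.0002
RP11-886H22.1	18	49814124	49814400	277	ACAA2	163	RP11-886H22.1	0	295	139	2.12	0.0001
CACNA1A	19	13298568	13298866	299	CTC-250I14.1	139779	CACNA1A	0	10268	5984	1.72	0.0001
CTD-3162L10.1	19	36304598	36304871	274	CTD-3162L10.1	0	LINC00665	8195	556	164	3.39	0.0001
APOE	19	44907737	44908015	279	APOE	0	CTB-129P6.7	1359	1028	1003	1.02	NS
CA11	19	48645763	48646036	274	DBP	8324	CA11	0	407	573	0.71	0.0002
SNRNP70	19	49107777	49108115	339	SNRNP70	0	LIN7B	6208	2096	1398	1.50	0.0001
CST3	20	23637606	23637888	283	CST9	31729	CST3	0	573	742	0.77	0.003
CHD6	20	41533110	41533383	274	RP4-620E11.5	150002	CHD6	0	1245	864	1.44	0.0001
FP671120.6	21	8258828	8259116	289	RNA5-8S5	1894	FP671120.6	0	1200	132	9.09	0.0001
FP236383.5	21	8435771	8435981	211	FP236383.5	0	FP236383.1	96	207	12	17.25	0.0001
APP	21	26021821	26022101	281	LLPHP2	258487	APP	0	1477	702	2.10	0.0001
CDR1	X	140784311	140784609	299	LINC00632	11631	CDR1	0	36675	62951	0.58	0.0001
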