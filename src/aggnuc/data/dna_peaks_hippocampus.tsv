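chrom	start	end	length	gene_5p	dist_5p	gene_3p	dist_3p	ad_peaks	amc_peaks	ad_p	amc_p
1	633735	634300	566	RP5-857K21.3	36236	RP5-857K21.4	0	1	4	4e-02	4e-06
1	143202361	143202903	543	RP11-344P13.1	21621836	CH17-333M13.2	140276	56	51	3e-29	9e-31
2	32916116	32916684	569	LINC00486	0	AL121656.5	10442	2	2	4e-11	2e-13
2	89830806	89831378	573	5S_rRNA	230125	IGKV2D-40	20412	11	11	2e-05	9e-06
3	75668953	75669543	591	DUX4L26	0	LINC00960	2847	1	1	4e-11	4e-11
3	93470298	93470861	564	HSPE1P19	3208589	RNU6-488P	372902	2	1	6e-57	1e-63
4	49149228	49149839	612	TPI1P4	132073	AC118282.3	47363	34	27	9e-11	1e-09
4	49711347	49711912	566	AC119751.4	111837	DCUN1D4	2131087	13	18	9e-16	7e-18
4	190179314	190179950	637	AC215524.1	4089	ABC7-42391500H16.3	5896	3	3	2e-13	3e-13
5	49661354	49661926	573	CTD-2013M15.1	3765383	EMB	734265	15	13	2e-11	1e-10
6	61322762	61323316	555	RP1-91N13.1	81450	MTRNR2L9	251011	1	1	3e-02	3e-06
7	59995570	59996144	575	RP11-548K12.13	2159318	RP11-715L17.1	2279216	0	9		2e-03
8	43237602	43238166	565	VN1R46P	16792	RP11-726G23.2	8588	4	4	4e-08	4e-09
9	70038064	70038625	562	RN7SL570P	153409	MAMDC2-AS1	0	1	1	8e-07	1e-05
10	42070370	42070986	617	RP11-96F8.1	3287261	KSR1P1	78323	39	35	9e-06	2e-04
10	133688058	133688661	604	AL845259.2	2945	DUX4L29	51944	2	2	2e-05	3e-04
12	35614697	35615271	575	AK6P1	1364738	RP11-125N22.4	1926740	1	1	8e-03	5e-05
13	18211736	18212297	562	AL356585.2	4266	RP11-341D18.4	41228	1	1	2e-11	6e-25
16	34063731	34064293	563	RP11-598D12.2	12369	CTD-2522B17.8	56176	5	5	7e-05	2e-04
16	34587942	34588505	564	BCLAF1P2	319292	CTD-2144E22.9	353471	15	16	8e-16	7e-18
16	46394505	46395067	563	PPP1R1AP2	10000000	ANKRD26P1	74273	16	12	3e-23	4e-23
17	21972876	21973349	474	KCNJ18	268263	AC144838.2	83237	9	7	8e-06	2e-06
17	26603641	26604283	643	RP11-846F4.11	3897955	RP11-260A9.1	377410	17	17	3e-12	1e-09
18	107991	108643	653	RP11-683L23.6	13660	ROCK1P1	421	1	2	1e-07	9e-10
18	110241	110848	608	ROCK1P1	0	MIR8078	1407	2	2	9e-09	2e-08
20	31241472	31242039	568	AC104301.2	339650	DEFB115	15624	17	13	3e-18	5e-16
21	7926020	7926634	615	SNORA11	99794	CH507-338C24.3	174616	3	3	9e-09	4e-09
21	8806909	8807490	582	SNX18P10	5028	bP-2189O9.1	38075	1	1	2e-04	1e-05
21	10269991	10270557	567	CH507-216K13.1	132986	AP003900.6	57853	1	4	5e-03	8e-06
21	10692593	10693162	570	IGHV1OR21-1	42757	AP001464.4	2306513	4	2	4e-15	6e-15
22	18896073	18896656	584	AC008103.4	11390	DGCR6	9371	1	1	2e-02	4e-05
X	156030320	156030900	581	DDX11L16	2442			1	1	1e-06	1e-06
Y	10746657	10747217	561	RNA5-8SP6	546350	RP1-85D24.4	295504	16	8	5e-05	1e-03
Y	11305019	11305652	634	AC134878.1	120061	DUX4L16	1265	6	4	1e-09	1e-10
Y	11312236	11312823	588	AC134882.1	3884	DUX4L17	2097	4	5	1e-08	8e-09
Y	11324443	11324950	508	DUX4L18	1619	DUX4L19	7378	8	8	3e-05	4e-05
Y	11721743	11722304	562	RP11-295P22.2	247505	RCC2P1	58747	8	8	1e-09	2e-08
Y	26638004	26638595	592	FAM58CP	10844	CTBP2P1	30000000	5	59	8e-03	3e-13
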