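name	gene_id	locus	protein_length	mw	pi	localization	est_number	heptapeptide	zf_type	domain_number	subgroup	homolog
PmWRKY01	LOC103330550	Pa1:1070280:1072953	590	64.75	6.98	Nucleus	1	WRKYGQK	C2H2	2	I	PpWRKY6
PmWRKY02	LOC103344588	Pa1:1909602:1912937	740	80.02	5.65	Nucleus	0	WRKYGQK	C2H2	2	I	PpWRKY5
PmWRKY03	LOC103331503	Pa1:13787725:13788689	239	27.20	9.03	Nucleus	0	WRKYGQK	C2H2	1	IIc	PpWRKY34
PmWRKY04	LOC103331584	Pa1:13972916:13975438	197	22.17	6.20	Nucleus	0	WRKYGKK	C2H2	1	IIc	PpWRKY35
PmWRKY05	LOC103337527	Pa1:19841802:19843058	326	35.77	9.60	Nucleus	1	WRKYGQK	C2H2	1	IId	PpWRKY41
PmWRKY06	LOC103339250	Pa1:20889375:20891243	297	33.36	5.03	Nucleus	0	WRKYGQK	C2H2	1	IIc	PpWRKY36
PmWRKY07	LOC103340389	Pa1:21713743:21716122	479	52.28	8.91	Nucleus	0	WRKYGQK	C2H2	2	I	PpWRKY7
PmWRKY08	LOC103342893	Pa1:22703478:22705201	335	37.41	5.76	Nucleus	0	WRKYGQK	C2HC	1	III	PpWRKY58
PmWRKY09	LOC103343421	Pa1:22717809:22719867	337	38.22	5.50	Nucleus	0	WRKYGQK	C2HC	1	III	PpWRKY57
PmWRKY10	LOC103343430	Pa1:22722643:22724633	340	37.98	5.67	Nucleus	0	WRKYGQK	C2HC	1	III	PpWRKY56
PmWRKY11	LOC103318654	Pa1:25540026:25541291	354	40.21	9.68	Nucleus	0	WRKYGQK	C2H2	1	IId	PpWRKY42
PmWRKY12	LOC103318792	Pa1:26409186:26413001	733	80.43	5.88	Nucleus	0	WRKYGQK	C2H2	2	I	PpWRKY9
PmWRKY13	LOC103319105	Pa2:1797770:1800086	562	62.09	5.17	Nucleus	0	WRKYGQK	C2H2	1	IIb	PpWRKY15
PmWRKY14	LOC103320106	Pa2:8913661:8915220	342	37.88	9.48	Nucleus	0	WRKYGQK	C2H2	1	IId	PpWRKY39
PmWRKY15	LOC103320368	Pa2:10410393:10411854	364	39.89	9.29	Nucleus	1	WRKYGQK	C2H2	1	IId	PpWRKY38
PmWRKY16	LOC103320597	Pa2:11611164:11611850	162	18.82	5.35	Nucleus	0	WRKYGKK	C2H2	1	IIc
PmWRKY17	LOC103320740	Pa2:12418544:12419976	285	31.68	8.33	Nucleus	0	WRKYGQK	C2H2	1	IIa	PpWRKY12
PmWRKY18	LOC103320741	Pa2:12424777:12426189	323	36.40	7.62	Nucleus	1	WRKYGQK	C2H2	1	IIa	PpWRKY11/Prupe.1G071400
PmWRKY19	LOC103321497	Pa2:16703139:16705510	330	36.38	6.00	Nucleus	0	WRKYGQK	C2H2	1	IIc	PpWRKY24
PmWRKY20	LOC103321524	Pa2:16839818:16842349	517	56.52	6.74	Nucleus	0	WRKYGQK	C2H2	2	I	PpWRKY1
PmWRKY21	LOC103321616	Pa2:17544191:17547389	643	70.06	6.43	Nucleus	0	WRKYGQK	C2H2	1	IIb	PpWRKY14
PmWRKY22	LOC103322097	Pa2:20999398:21001199	162	18.46	9.67	Nucleus	0	WRKYGQK	C2H2	1	IIc	PpWRKY23
PmWRKY23	LOC103323186	Pa2:32805980:32807604	390	43.02	5.82	Nucleus	0	WRKYGQK	C2H2	1	IIc	PpWRKY22
PmWRKY24	LOC103324471	Pa3:408956:411939	591	64.44	7.06	Nucleus	1	WRKYGQK	C2H2	1	IIb	PpWRKY20
PmWRKY25	LOC103324889	Pa3:2860917:2862029	280	30.55	5.45	Nucleus	0	WRKYGQK	C2H2	1	IIe	PpWRKY47
PmWRKY26	LOC103325015	Pa3:3723897:3725432	340	37.69	6.55	Nucleus	0	WRKYGQK	C2H2	1	IIc	PpWRKY32
PmWRKY27	LOC103325306	Pa3:5613186:5615990	515	55.88	6.07	Nucleus	0	WRKYGQK	C2H2	1	IIe	PpWRKY48/Prupe.1G114800
PmWRKY28	LOC103326420	Pa3:13640842:13643362	547	59.91	6.13	Nucleus	0	WRKYGQK	C2H2	1	IIb	PpWRKY19
PmWRKY29	LOC103326493	Pa3:13656379:13658843	544	59.51	6.02	Nucleus	0	WRKYGQK	C2H2	1	IIb	PpWRKY19
PmWRKY30	LOC103326638	Pa3:15399255:15407416	884	98.18	6.98	Nucleus	0	WRKYGQK	C2H2	2	I	PpWRKY4
PmWRKY31	LOC103327251	Pa4:195608:198391	616	67.23	6.42	Nucleus	0	WRKYGQK	C2H2	1	IIb	PpWRKY16
PmWRKY32	LOC103327303	Pa4:564486:565902	321	35.77	6.51	Nucleus	0	WRKYGQK	C2H2	1	IIc	PpWRKY29
PmWRKY33	LOC103328175	Pa4:6725543:6727134	320	35.25	8.71	Nucleus	1	WRKYGQK	C2H2	1	IIa	PpWRKY13
PmWRKY34	LOC103328332	Pa4:8491309:8494074	268	29.42	5.37	Nucleus	0	WRKYGQK	C2H2	1	IIe	PpWRKY46/Purpe.2G185100
PmWRKY35	LOC103328791	Pa4:14169139:14171554	367	41.67	7.10	Nucleus	1	WRKYGQK	C2H2	1	IIc	PpWRKY30
PmWRKY36	LOC103329228	Pa4:16910810:16913287	486	53.04	5.90	Nucleus	0	WRKYGQK	C2H2	2	I	PpWRKY2
PmWRKY37	LOC103329304	Pa4:17519417:17521899	649	70.74	6.11	Nucleus	0	WRKYGQK	C2H2	1	IIb	PpWRKY17
PmWRKY38	LOC103329978	Pa4:21736698:21738977	499	54.64	6.71	Nucleus	0	WRKYGQK	C2H2	1	IIb	PpWRKY18/Prupe.1G393000
PmWRKY39	LOC103330053	Pa4:22207825:22211049	533	58.44	8.45	Nucleus	0	WRKYGQK	C2H2	2	I	PpWRKY3
PmWRKY40	LOC103331676	Pa5:13956787:13959777	244	27.79	7.29	Nucleus	0	WRKYGQK	C2H2	1	IIc	PpWRKY26
PmWRKY41	LOC103332060	Pa5:16864359:16866293	221	24.84	9.24	Nucleus	0	WRKYGQK	C2H2	1	IIc	PpWRKY27
PmWRKY42	LOC103332064	Pa5:16887019:16890355	417	46.73	7.72	Nucleus	0	WRKYGQK	C2H2	1	IIe	PpWRKY44
PmWRKY43	LOC103332261	Pa5:18120250:18122148	357	39.80	4.90	Nucleus	1	WRKYGQK	C2HC	1	III	PpWRKY51
PmWRKY44	LOC103332696	Pa5:20443902:20444645	209	24.04	9.05	Nucleus	0	WRKYGQK	C2H2	1	IIc	PpWRKY28
PmWRKY45	LOC103333076	Pa5:21989132:21991115	344	37.86	5.78	Nucleus	0	WRKYGQK	C2HC	1	III	PpWRKY52
PmWRKY46	LOC103333154	Pa5:23138449:23140440	323	36.46	5.70	Nucleus	0	WRKYGQK	C2HC	1	III	PpWRKY53/Purpe.2G307400
PmWRKY47	LOC103333772	Pa5:25721161:25722357	332	36.12	5.32	Nucleus	0	WRKYGQK	C2HC	1	III	PpWRKY54
PmWRKY48	LOC103333707	Pa5:25986620:25987499	228	24.63	4.92	Nucleus	0	WRKYGQK	C2H2	1	IIe	PpWRKY45
PmWRKY49	LOC103334065	Pa6:994260:995360	242	28.23	6.02	Nucleus	0	WRKYGQK	C2H2	1	IIe	PpWRKY50
PmWRKY50	LOC103334153	Pa6:1797284:1799454	355	40.24	9.61	Nucleus	0	WRKYGQK	C2H2	1	IId	PpWRKY43
PmWRKY51	LOC103335291	Pa6:8182262:8186226	471	52.51	7.88	Chlo, Nucl	0	WRKYGQK	C2H2	1	IIx	ppa024204
PmWRKY52	LOC103337200	Pa7:5945463:5947021	330	37.05	9.68	Nucleus	0	WRKYGQK	C2H2	1	IId	PpWRKY40
PmWRKY53	LOC103337694	Pa7:9472026:9473037	291	32.89	5.23	Nucleus	0	WRKYGQK	C2H2	1	IIe	PpWRKY49
PmWRKY54	LOC103337660	Pa7:10206830:10208250	356	40.00	5.41	Nucleus	0	WRKYGQK	C2HC	1	III	PpWRKY55
PmWRKY55	LOC103338090	Pa7:12882417:12883702	170	19.52	9.35	Nucleus	0	WRKYGQK	C2H2	1	IIc	PpWRKY33/Prupe.6G286000
PmWRKY56	LOC103338408	Pa7:14366251:14369593	683	73.58	6.45	Nucleus	0	WRKYGQK	C2H2	1	IIb	PpWRKY21
PmWRKY57	LOC103341266	Pa8:16767252:16770984	537	59.39	5.47	Nucleus	0	WRKYGQK	C2H2	2	I	PpWRKY10
PmWRKY58	LOC103342913	scaffold22:94704:96740	536	59.89	6.82	Nucleus	1	WRKYGQK	C2H2	2	I	PpWRKY8
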