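Name	Locus	Chromosome	Heptapeptide	ZincFingerType	DomainCount	Group	pI	Mw_kDa	ProteinLength_aa	CDSLength_bp	ExonCount
StWRKY01	PGSC0003DMG400011457	chr01	WRKYGQK	C2H2	1	IIc	4.97	37.28	339	1020	3
StWRKY02	PGSC0003DMG400009014	chr01	WRKYGQK	C2H2	1	IIe	5.20	27.22	244	735	3
StWRKY03	PGSC0003DMG400009051	chr01	WRKYGQK	C2H2	1	IIc	6.07	35.88	317	954	3
StWRKY04	PGSC0003DMG400031175	chr01	WRKYGQK	C2H2	1	IIc	8.16	27.50	251	756	4
StWRKY05	PGSC0003DMG400000064	chr01	WRKYGQK	C2H2	1	IIe	5.73	38.83	352	1059	3
StWRKY06	PGSC0003DMG400000211	chr01	WRKYGQK	C2HC	1	III	5.64	38.87	346	1041	3
StWRKY07	PGSC0003DMG400029779	chr01	WRKYGQK	C2H2	1	IIb	8.14	45.94	413	1242	4
StWRKY08	PGSC0003DMG400015104	chr02	WRKYGQK	C2H2	1	IIe	5.16	46.16	413	1242	3
StWRKY09	PGSC0003DMG400022063	chr02	WRKYGQK	C2H2	1	IIb	7.02	55.21	496	1491	5
StWRKY10	PGSC0003DMG400025481	chr02	WRKYGQK	C2H2	1	IId	9.12	37.38	334	1005	3
StWRKY11	PGSC0003DMG402006935	chr02	WRKYGQK	C2H2	1	IIb	6.29	48.68	443	1332	3
StWRKY12	PGSC0003DMG400009703	chr02	WRKYGQK	C2H2	1	IIc	6.49	36.17	318	957	3
StWRKY13	PGSC0003DMG400028469	chr02	WRKYGQK	C2H2	1	IIe	5.94	33.57	299	900	3
StWRKY14	PGSC0003DMG400016441	chr02	WRKYGQK	C2H2	1	IIb	6.98	60.06	553	1662	6
StWRKY15	PGSC0003DMG400024961	chr02	WRKYGQK	C2H2	1	IId	9.70	36.01	324	975	3
StWRKY16	PGSC0003DMG400001434	chr02	WRKYGQK/WRKYGQK	C2H2	2	I	6.13	50.16	451	1356	4
StWRKY17	PGSC0003DMG400020206	chr02	WRKYGQK	C2H2	1	IIc	9.52	16.45	141	426	2
StWRKY18	PGSC0003DMG401005575	chr03	WRKYGQK/WRKYGQK	C2H2	2	I	6.56	57.08	516	1551	4
StWRKY19	PGSC0003DMG400020608	chr03	WRKYGQK	C2HC	1	III	6.17	31.89	277	834	3
StWRKY20	PGSC0003DMG400041197	chr03	WRKYGQK	C2H2	1	IIe	8.46	28.69	249	750	3
StWRKY21	PGSC0003DMG400039175	chr03	WRKCGQK	C2H2	1	IIe	8.89	28.66	249	750	3
StWRKY22	PGSC0003DMG400009103	chr03	WRKYGQK	C2HC	1	III	5.90	40.31	356	1071	3
StWRKY23	PGSC0003DMG400044842	chr03	WRKYGMK	C2H2	1	IIe	6.06	29.51	259	780	1
StWRKY24	PGSC0003DMG400034476	chr03	WKKHGSN	C2H2	1	IIe	7.06	19.99	173	552	1
StWRKY25	PGSC0003DMG400018081	chr03	WRKYGQK	C2H2	1	IIb	6.82	58.45	525	1578	5
StWRKY26	PGSC0003DMG400019824	chr03	WRKYGQK	C2H2	1	IIa	8.74	39.76	355	1068	5
StWRKY27	PGSC0003DMG400040494	chr04	WRKYGQK	C2H2	1	IIe	8.86	35.67	311	936	5
StWRKY28	PGSC0003DMG401031196	chr04	WRKYGKK	C2H2	1	IIc	9.47	16.12	138	417	3
StWRKY29	PGSC0003DMG400019706	chr04	WRKYGQK	C2H2	1	IIc	9.00	27.26	234	705	3
StWRKY30	PGSC0003DMG400031140	chr04	WRKYGKK	C2H2	1	IIc	6.55	26.68	231	696	3
StWRKY31	PGSC0003DMG400007947	chr04	WRKYGQK	C2H2	1	IId	9.67	38.88	354	1065	3
StWRKY32	PGSC0003DMG400028335	chr05	WRKYGQK/WRKYGQK	C2H2	2	I	8.05	55.46	508	1527	4
StWRKY33	PGSC0003DMG400028381	chr05	WRKYGQK	C2H2	1	IIc	5.34	35.28	326	981	3
StWRKY34	PGSC0003DMG400021895	chr05	WRKYGQK	C2H2	1	IIc	9.22	19.92	172	519	2
StWRKY35	PGSC0003DMG400036639	chr05	WRKYGQK	C2H2	1	IIe	9.53	37.44	330	993	3
StWRKY36	PGSC0003DMG400035855	chr05	WRKYGQK	C2H2	1	IIe	9.04	37.55	330	993	3
StWRKY37	PGSC0003DMG400033884	chr05	WRKYGQR	C2HC	1	III	6.25	32.92	294	885	3
StWRKY38	PGSC0003DMG401033880	chr05	WRKYGQK	C2HC	1	III	5.83	37.37	331	996	3
StWRKY39	PGSC0003DMG400017990	chr05	WRKYGQK	C2HC	1	III	5.48	34.06	301	906	3
StWRKY40	PGSC0003DMG400027208	chr05	WRKYGQK	C2H2	1	IIc	9.01	28.14	250	753	3
StWRKY41	PGSC0003DMG400023360	chr05	WRKYGQK/WRKYGQK	C2H2	2	I	6.84	51.90	457	1374	3
StWRKY42	PGSC0003DMG400005329	chr06	WRKYGQK	C2H2	1	IId	9.62	39.95	355	1068	3
StWRKY43	PGSC0003DMG400008776	chr06	WRKYGQK	C2HC	1	III	5.94	38.15	347	1044	4
StWRKY44	PGSC0003DMG400027582	chr06	WRKYGQK	C2HC	1	III	8.06	26.02	223	672	3
StWRKY45	PGSC0003DMG400016769	chr06	WRKYGQK/WRKYGQK	C2H2	2	I	6.90	59.57	534	1605	5
StWRKY46	PGSC0003DMG400028520	chr06	WRKYGQK	C2H2	1	IIa	8.37	39.79	360	1083	4
StWRKY47	PGSC0003DMG400006155	chr07	WRKYGQK/WRKYGQK	C2H2	2	I	6.55	46.54	422	1269	4
StWRKY48	PGSC0003DMG400015015	chr07	WRKYGQK	C2H2	1	IIb	6.09	60.26	557	1674	5
StWRKY49	PGSC0003DMG400020432	chr07	WRKYGQK	C2H2	1	IIe	5.51	28.19	256	771	4
StWRKY50	PGSC0003DMG400017349	chr07	WRKYGQK	C2H2	1	IIc	6.26	36.29	319	960	3
StWRKY51	PGSC0003DMG400022290	chr07	WRKYGQK/WRKYGQK	C2H2	2	I	7.05	64.91	596	1791	6
StWRKY52	PGSC0003DMG400022143	chr07	WRKYGQK/WRKYGQK	C2H2	2	I	6.01	81.04	748	2247	5
StWRKY53	PGSC0003DMG400009530	chr08	WRKYGQK	C2H2	1	IId	9.62	36.33	334	1005	3
StWRKY54	PGSC0003DMG400005835	chr08	WRKYGQK	C2HC	1	III	5.69	40.74	360	1083	3
StWRKY55	PGSC0003DMG400005836	chr08	WRKYGQK	C2HC	1	III	6.89	34.07	305	918	3
StWRKY56	PGSC0003DMG400008188	chr08	WRKYGKK	C2H2	1	IIc	4.79	14.65	128	387	2
StWRKY57	PGSC0003DMG402007388	chr08	WRKYGQK	C2H2	1	IIa	8.84	28.72	253	762	4
StWRKY58	PGSC0003DMG400007387	chr08	WRKYGQK	C2H2	1	IIa	5.70	29.74	261	786	4
StWRKY59	PGSC0003DMG400012318	chr08	WRKYGQK	C2H2	1	IIe	5.57	35.04	307	924	3
StWRKY60	PGSC0003DMG400012317	chr08	WRKYGQK	C2H2	1	IIc	9.13	26.17	228	687	2
StWRKY61	PGSC0003DMG400012160	chr08	WRKYGQK	C2HC	1	III	5.40	38.57	339	1020	3
StWRKY62	PGSC0003DMG400011633	chr09	WRKYGQK/WRKYGQK	C2H2	2	I	7.05	45.47	408	1227	4
StWRKY63	PGSC0003DMG400029207	chr09	WRKYGQK	C2HC	1	III	5.63	33.46	293	882	3
StWRKY64	PGSC0003DMG400015076	chr09	WRKYGQK	C2H2	1	IId	9.65	39.10	346	1041	3
StWRKY65	PGSC0003DMG400011271	chr10	WIKYGEN/WRKYGQK	C2H2	2	I	5.07	75.77	697	2094	5
StWRKY66	PGSC0003DMG401010558	chr10	WRKYGQK	C2H2	1	IIe	8.36	23.24	208	627	3
StWRKY67	PGSC0003DMG400019884	chr10	WRKYGQK	C2HC	1	III	5.55	33.52	290	873	3
StWRKY68	PGSC0003DMG400019408	chr10	WRKYGQK	C2H2	1	IIe	4.73	26.70	238	717	3
StWRKY69	PGSC0003DMG400008391	chr10	WRKYGQK	C2HC	1	III	8.94	25.43	218	657	3
StWRKY70	PGSC0003DMG400010987	chr10	WRKYGQK/WRKYGQK	C2H2	2	I	9.51	52.05	467	1404	5
StWRKY71	PGSC0003DMG400007788	chr12	WRKYGKK	C2H2	1	IIc	6.56	37.68	334	1005	3
StWRKY72	PGSC0003DMG400037700	chr12	WHKCGQK	C2H2	1	IIe	8.11	37.51	331	996	3
StWRKY73	PGSC0003DMG402028822	chr12	WRKYGQK/WRKYGQK	C2H2	2	I	6.62	60.48	549	1650	4
StWRKY74	PGSC0003DMG400029815	chr12	WRKYGQK/WRKYGQK	C2H2	2	I	6.37	65.80	611	1836	6
StWRKY75	PGSC0003DMG400028633	chr12	WRKYGQK	C2H2	1	IIa	9.52	24.70	217	654	4
StWRKY76	PGSC0003DMG400023196	chr12	WRKYGKK	C2H2	1	IIc	8.28	24.90	213	642	3
StWRKY77	PGSC0003DMG400016957	chr12	WRKYGKK	C2H2	1	IIc	9.35	14.57	124	375	2
StWRKY78	PGSC0003DMG400029371	chr12	WRKYGQK	C2H2	1	IId	9.61	34.03	312	939	3
StWRKY79	PGSC0003DMG400033177	chr00	WRKYGKK	C2H2	1	IIc	9.23	12.10	102	309	2
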