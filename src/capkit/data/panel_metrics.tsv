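#specimen	species	genus_group	accession	sequence_yield	on_target_yield	on_target_pct	cp_yield	cp_pct	cp_depth	cp_pct_covered	n_base_pct
C_angustifolia_88	C_angustifolia	in_genus	SRS3532111	1515526	488207	32.2	248243	16.4	157	100.0	0.1
C_angustifolia_143	C_angustifolia	in_genus	SRS3532109	8462020	3191296	37.7	901138	10.6	568	100.0	0.1
C_fissilis_9	C_fissilis	in_genus	SRS3532073	1174195	286398	24.4	93257	7.9	59	99.9	0.2
C_fissilis_19	C_fissilis	in_genus	SRS3531955	5431374	2122651	39.1	333680	6.1	210	99.9	0.2
C_fissilis_112	C_fissilis	in_genus	SRS3532019	1750937	376881	21.5	151391	8.6	96	99.8	0.4
C_fissilis_130	C_fissilis	in_genus	SRS3532093	5351355	2154295	40.3	135883	2.5	86	99.9	0.2
C_fissilis_140	C_fissilis	in_genus	SRS3532018	12183129	5047225	41.4	403902	3.3	255	100.0	0.1
C_fissilis_211	C_fissilis	in_genus	SRS3532001	1272124	259059	20.4	167826	13.2	106	100.0	0.2
C_fissilis_230	C_fissilis	in_genus	SRS3532122	3251712	1183526	36.4	106353	3.3	67	99.9	0.4
C_fissilis_254	C_fissilis	in_genus	SRS3532102	17394724	5583057	32.1	643227	3.7	405	100.0	0.1
C_fissilis_264	C_fissilis	in_genus	SRS3532060	19290108	7776152	40.3	356979	1.9	225	100.0	0.1
C_fissilis_292	C_fissilis	in_genus	SRS3532121	7116518	2752495	38.7	1866075	26.2	1176	100.0	0.1
C_montana_50	C_montana	in_genus	SRS3532121	5561468	2026840	36.4	577438	10.4	364	100.0	0.2
C_odorata_10	C_odorata	in_genus	SRS3532068	4009101	1472131	36.7	273812	6.8	173	99.8	0.4
C_odorata_52	C_odorata	in_genus	SRS3532030	12254507	4791273	39.1	618594	5.0	390	100.0	0.1
C_odorata_162	C_odorata	in_genus	SRS3531967	8942300	3574795	40.0	756725	8.5	477	100.0	0.1
C_odorata_185	C_odorata	in_genus	SRS3532120	5713214	2177026	38.1	382876	6.7	241	100.0	0.1
C_odorata_202	C_odorata	in_genus	SRS3532089	6372915	2366009	37.1	116791	1.8	74	99.7	0.4
C_odorata_222	C_odorata	in_genus	SRS3532005	10421206	4017316	38.5	289695	2.8	183	99.8	0.3
C_odorata_277	C_odorata	in_genus	SRS3531957	6794076	2539070	37.4	309154	4.6	195	99.8	0.5
C_odorata_287	C_odorata	in_genus	SRS3532135	438310	6566	1.5	35604	8.1	25	90.2	7.7
C_saltensis_75	C_saltensis	in_genus	SRS3532020	29081506	10692874	36.8	831948	2.9	524	100.0	0.1
C_saltensis_102	C_saltensis	in_genus	SRS3532010	5252123	2107682	40.1	672165	12.8	424	100.0	0.1
C_saltensis_186	C_saltensis	in_genus	SRS3532110	1829249	554830	30.3	125974	6.9	79	100.0	0.2
G_guidonia_2	G_guidonia	out_genus	SRS3532153	5211243	68501	1.3	92122	1.8	78	74.2	19.5
G_guidonia_4	G_guidonia	out_genus	SRS3532152	6710368	100652	1.5	129500	1.9	105	77.8	13.9
G_guidonia_7	G_guidonia	out_genus	SRS3532151	6850155	101252	1.5	81731	1.2	74	69.8	17.8
G_guidonia_9	G_guidonia	out_genus	SRS3532150	14213046	206827	1.5	197446	1.4	139	89.3	13.5
G_guidonia_10	G_guidonia	out_genus	SRS3532124	7833412	91070	1.2	69582	0.9	69	63.9	15.0
G_guidonia_11	G_guidonia	out_genus	SRS3532123	9166583	123598	1.3	279357	3.0	194	90.9	7.3
G_guidonia_13	G_guidonia	out_genus	SRS3532149	9909255	133845	1.4	259749	2.6	184	88.9	7.6
G_guidonia_15	G_guidonia	out_genus	SRS3532148	10634632	148498	1.4	267334	2.5	185	91.1	7.6
G_guidonia_17	G_guidonia	out_genus	SRS3532147	10900380	128635	1.2	138537	1.3	108	80.8	13.3
G_guidonia_19	G_guidonia	out_genus	SRS3532146	16194976	195256	1.2	342985	2.1	229	94.5	8.3
S_mahagoni_21	S_mahagoni	out_genus	SRS3532156	16927562	1051671	6.2	1530129	9.0	966	99.8	1.5
S_mahagoni_22	S_mahagoni	out_genus	SRS3532155	18098858	1113548	6.2	3806990	21.0	2399	100.0	0.5
T_tuberculata_1	T_tuberculata	out_genus	SRS3531991	3823599	39222	1.0	54256	1.4	159	89.8	17.1
T_tuberculata_3	T_tuberculata	out_genus	SRS3531995	5915718	60793	1.0	92170	1.6	76	76.4	14.2
T_tuberculata_6	T_tuberculata	out_genus	SRS3531996	6159511	63116	1.0	140155	2.3	110	80.0	11.4
T_tuberculata_8	T_tuberculata	out_genus	SRS3531994	6595654	70395	1.1	59560	0.9	50	74.4	23.5
T_tuberculata_12	T_tuberculata	out_genus	SRS3531993	11354222	92063	0.8	283424	2.5	56	60.9	8.3
T_tuberculata_18	T_tuberculata	out_genus	SRS3531989	10145721	103682	1.0	225870	2.2	196	91.3	12.2
T_tuberculata_20	T_tuberculata	out_genus	SRS3531990	8374551	91146	1.1	117705	1.4	90	82.5	13.2
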