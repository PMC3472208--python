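gene_id	nonsyn_length	syn_length	nonsyn	syn	kaks
Eucgr.B02730	258	120	11	0	5.6
Eucgr.E04298	494	194	10	0	4.3
Eucgr.J02063	240	111	15	1	3.7
Eucgr.H04702	312	126	8	0	3.6
Eucgr.B02265	353	166	6	0	3.3
Eucgr.F04064	129	60	6	0	3.3
Eucgr.H04620	312	141	6	0	3.2
Eucgr.D01191	841	398	12	1	3.1
Eucgr.D01723	537	231	28	3	3.1
Eucgr.C02248	151	65	6	0	3
Eucgr.A01862	419	187	12	1	2.9
Eucgr.H03577	348	153	12	1	2.9
Eucgr.D01717	385	152	6	0	2.8
Eucgr.B02882	357	159	5	0	2.7
Eucgr.G00701	103	47	5	0	2.7
Eucgr.K01312	362	163	5	0	2.7
Eucgr.J03180	349	149	5	0	2.6
Eucgr.B03466	405	171	11	1	2.5
Eucgr.F00424	426	177	11	1	2.5
Eucgr.I01743	145	59	5	0	2.5
Eucgr.G01464	61	29	4	0	2.4
Eucgr.C00195	311	142	4	0	2.3
Eucgr.K02172	796	329	27	4	2.3
Eucgr.D01225	367	161	4	0	2.2
Eucgr.K01587	505	233	18	3	2.2
Eucgr.G02486	272	112	4	0	2.1
Eucgr.H04886	638	265	9	1	2.1
Eucgr.I01744	123	51	4	0	2.1
Eucgr.L02163	143	61	9	1	2.1
Eucgr.C01903	219	90	4	0	2
Eucgr.F01425	160	65	4	0	2
Eucgr.I01164	351	156	8	1	2
Eucgr.C02013	720	331	28	6	1.9
Eucgr.E01742	103	48	3	0	1.9
Eucgr.G00935	80	31	4	0	1.9
Eucgr.I02449	307	134	12	2	1.9
Eucgr.J03046	168	78	3	0	1.9
Eucgr.A02694	128	59	3	0	1.8
Eucgr.B01852	339	138	12	2	1.8
Eucgr.B02741	317	142	7	1	1.8
Eucgr.D02113	186	84	3	0	1.8
Eucgr.E00479	58	26	3	0	1.8
Eucgr.F03056	1150	473	12	2	1.8
Eucgr.H02910	254	106	12	2	1.8
Eucgr.A02080	67	29	3	0	1.7
Eucgr.B03040	176	76	3	0	1.7
Eucgr.D00574	477	208	3	0	1.7
Eucgr.D01956	605	250	7	1	1.7
Eucgr.F03511	188	79	3	0	1.7
Eucgr.H03533	55	23	3	0	1.7
Eucgr.I00325	221	91	3	0	1.7
Eucgr.L03100	466	194	3	0	1.7
Eucgr.B03756	184	74	3	0	1.6
Eucgr.C00342	193	80	14	3	1.6
Eucgr.D00603	111	46	3	0	1.6
Eucgr.E00452	400	164	3	0	1.6
Eucgr.E03921	254	107	14	3	1.6
Eucgr.E04006	104	43	3	0	1.6
Eucgr.F00810	31	17	2	0	1.6
Eucgr.F02734	205	83	3	0	1.6
Eucgr.G02336	616	269	14	3	1.6
Eucgr.G02823	394	159	3	0	1.6
Eucgr.G03355	724	311	18	4	1.6
Eucgr.H00155	459	183	15	3	1.6
Eucgr.H00996	111	45	3	0	1.6
Eucgr.H01946	252	99	3	0	1.6
Eucgr.H04711	189	75	3	0	1.6
Eucgr.H05152	281	115	3	0	1.6
Eucgr.K01016	236	106	13	3	1.6
Eucgr.L03046	171	78	6	1	1.6
Eucgr.A01283	476	190	10	2	1.5
Eucgr.C02545	651	261	10	2	1.5
Eucgr.C03738	53	19	3	0	1.5
Eucgr.E00907	198	87	6	1	1.5
Eucgr.E02617	80	40	2	0	1.5
Eucgr.E03833	453	195	6	1	1.5
Eucgr.F00172	57	21	3	0	1.5
Eucgr.F01135	1007	418	10	2	1.5
Eucgr.F01523	66	24	3	0	1.5
Eucgr.F01700	152	58	3	0	1.5
Eucgr.F04454	254	97	3	0	1.5
Eucgr.G00423	159	69	6	1	1.5
Eucgr.G01862	673	317	15	4	1.5
Eucgr.H02734	30	15	2	0	1.5
Eucgr.I00883	829	362	36	10	1.5
Eucgr.I01025	2	1	2	0	1.5
Eucgr.J00894	163	62	3	0	1.5
Eucgr.J02210	760	326	6	1	1.5
Eucgr.K01084	101	49	2	0	1.5
Eucgr.L01514	81	30	3	0	1.5
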