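gene_id	pos	control_a	control_b	control_freq	stress_a	stress_b	stress_freq	snp_annotation
Eucgr.I01495	25151384	36	1	0.97	15	589	0.02	syn
Eucgr.I02395	34587565	10	3	0.77	40	85	0.32	5'UTR
Eucgr.I02395	34586749	8	16	0.33	177	6804	0.03	non-syn
Eucgr.F00644	8551578	5	44	0.10	56	2036	0.03	non-syn
Eucgr.D00606	11184666	6	3	0.67	33	266	0.11	syn
Eucgr.B03987	63762855	22	25	0.47	111	430	0.21	3'UTR
Eucgr.B03987	63762861	20	29	0.41	96	382	0.20	3'UTR
Eucgr.A02790	38441055	8	2	0.80	121	579	0.17	non-syn
Eucgr.A02790	38441184	4	11	0.27	31	738	0.04	non-syn
Eucgr.C01388	22208472	1114	155	0.88	8	7	0.53	syn
Eucgr.I01393	24399270	28	1	0.97	39	158	0.20	non-syn
Eucgr.I01393	24399277	28	3	0.90	40	162	0.20	non-syn
Eucgr.I01393	24399018	4	6	0.40	205	11	0.95	non-syn
Eucgr.C01031	16478607	7	6	0.54	101	748	0.12	syn
Eucgr.H00189	1874619	7	1	0.88	6	94	0.06	syn
Eucgr.G01188	19918572	5	12	0.29	24	390	0.06	syn
Eucgr.K01389	17036132	49	19	0.72	259	1030	0.20	syn
Eucgr.K01389	17035852	7	53	0.12	34	1275	0.03	5'UTR
Eucgr.K01389	17035854	21	34	0.38	797	547	0.59	5'UTR
Eucgr.K01389	17036141	16	51	0.24	817	386	0.68	syn
Eucgr.E03875	67744315	114	123	0.48	6	28	0.18	non-syn
Eucgr.C02590	49489875	35	1	0.97	87	324	0.21	non-syn
Eucgr.C02590	49489315	14	0	1.00	26	62	0.30	5'UTR
Eucgr.C02590	49489916	54	1	0.98	153	271	0.36	non-syn
Eucgr.C02590	49489924	55	2	0.96	154	242	0.39	syn
Eucgr.C02590	49489939	15	7	0.68	39	211	0.16	syn
Eucgr.A02077	31568814	24	22	0.52	177	435	0.29	non-syn
Eucgr.I01579	25696053	36	5	0.88	10	18	0.36	syn
Eucgr.I01579	25696038	30	4	0.88	15	17	0.47	syn
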