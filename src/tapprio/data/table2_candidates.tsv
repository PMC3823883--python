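Rank	Entrez Gene ID	HGNC Symbol	Parkin ND	MonogenicPD ND	MonogenicPD #ND	iMonogenicPD	Not Complex	Pink1 TAP	HNet Degree	GOComp	FunSim MonogenicPD	GOSlimPD	ParkinGS	Pink1GS	CalmodulinIP	Selection Level
1	5071	PARK2	0	0	1	PARK2	–	–	76	true	true	–	true	true	–	0
2	3301	DNAJA1	1	1	2	PARK2, UCHL1	–	–	551	true	–	true	true	–	true	0
3	3303	HSPA1A	1	1	2	PARK2, SNCA	–	true	926	–	true	true	true	true	true	0
4	3312	HSPA8	1	1	2	PARK2, UCHL1	–	true	1292	true	–	true	true	true	true	0
5	5052	PRDX1	2	1	2	UCHL1, PARK7	–	–	559	–	–	true	–	–	true	1
6	801	CALM1	2	1	2	UCHL1, SNCA	–	–	780	–	–	–	true	true	true	1
7	3181	HNRNPA2B1	2	1	2	UCHL1, PARK7	–	–	848	–	–	–	–	–	true	1
8	10845	CLPX	2	1	1	PARK7	–	–	161	true	true	–	true	true	–	2
9	10951	CBX1	3	1	1	UCHL1	–	–	235	–	true	–	true	true	–	2
10	3329	HSPD1	2	1	1	PARK7	–	true	904	true	true	true	true	true	true	2
11	60	ACTB	2	1	1	UCHL1	–	–	1016	true	true	true	true	true	true	2
12	492	ATP2B3	3	3	8	0	true	–	2	–	true	true	–	–	–	3
13	9868	TOMM70A	2	2	5	0	true	–	8	true	true	true	–	–	–	3
14	490	ATP2B1	3	2	2	0	true	–	8	–	true	true	–	–	true	3
15	23581	CASP14	3	2	5	0	–	–	29	–	true	true	true	–	–	3
16	3005	H1F0	2	2	4	0	–	–	74	–	true	true	–	–	true	3
17	7818	DAP3	2	2	7	0	–	–	125	true	true	true	–	–	–	3
18	5589	PRKCSH	2	2	5	0	–	–	127	true	true	true	true	true	true	3
19	84790	TUBA1C	2	1	1	UCHL1	–	true	266	true	–	–	true	–	true	3
20	9131	AIFM1	2	2	8	0	–	–	333	–	true	true	true	true	true	3
21	10128	LRPPRC	2	1	1	PARK7	–	true	461	true	–	–	true	true	–	3
22	213	ALB	2	1	1	UCHL1	–	–	587	true	–	true	–	–	true	3
23	10383	TUBB4B	2	1	1	UCHL1	–	–	599	true	–	true	–	true	true	3
24	7431	VIM	2	1	1	SNCA	–	–	635	–	–	true	–	–	true	3
25	7277	TUBA4A	2	1	1	UCHL1	–	–	733	true	–	true	–	–	true	3
26	3326	HSP90AB1	2	1	1	LRRK2	–	true	739	true	–	true	–	–	true	3
27	3320	HSP90AA1	2	1	1	UCHL1	–	true	757	true	–	true	–	–	true	3
28	3313	HSPA9	2	1	1	UCHL1	–	true	778	true	–	true	true	true	true	3
29	4869	NPM1	2	1	1	PARK7	–	–	813	true	–	true	–	–	true	3
30	203068	TUBB	2	1	1	UCHL1	–	true	889	true	–	–	–	true	true	3
31	3309	HSPA5	2	1	1	UCHL1	–	true	921	true	–	true	–	–	true	3
32	284110	GSDMA	–	–	–	0	–	–	–	–	true	true	–	–	–	3
33	9939	RBM8A	2	1	1	UCHL1	–	–	245	true	–	–	true	true	–	4
34	813	CALU	2	1	1	UCHL1	–	–	266	true	–	–	true	true	true	4
35	5955	RCN2	2	1	1	UCHL1	–	–	297	–	–	–	true	true	true	4
36	10240	MRPS31	2	1	1	PARK7	–	–	365	–	–	–	true	true	–	4
37	2597	GAPDH	2	1	1	UCHL1	–	–	595	–	–	–	true	true	true	4
38	5250	SLC25A3	2	1	1	UCHL1	–	–	597	–	–	–	true	true	true	4
39	498	ATP5A1	2	1	1	UCHL1	–	–	611	true	–	–	true	–	true	4
40	3032	HADHB	2	1	1	UCHL1	–	–	675	–	–	–	–	true	true	4
41	1915	EEF1A1	2	1	1	UCHL1	–	–	1079	–	–	–	true	true	true	4
42	4747	NEFL	2	1	1	UCHL1	–	–	37	true	–	–	–	–	–	5
43	84617	TUBB6	2	1	1	UCHL1	–	–	174	true	–	–	–	–	true	5
44	10165	SLC25A13	2	1	1	PARK7	–	–	648	true	–	–	–	–	true	5
45	221613	HIST1H2AA	3	2	1	0	true	–	8	–	true	–	–	–	–	6
46	539	ATP5O	2	2	6	0	–	–	63	true	true	–	true	true	–	6
47	51081	MRPS7	2	2	6	0	–	–	128	–	true	–	true	–	–	6
48	6418	SET	2	2	7	0	–	–	169	true	true	–	true	true	–	6
49	4976	OPA1	2	2	6	0	–	–	177	true	true	–	true	true	true	6
50	4741	NEFM	2	1	1	UCHL1	–	–	233	–	–	–	–	–	true	6
51	11335	CBX3	2	2	5	0	–	–	256	–	true	–	true	true	–	6
52	1975	EIF4B	2	2	8	0	–	–	300	–	true	–	–	–	–	6
53	9532	BAG2	2	2	8	0	–	–	351	true	true	–	true	true	true	6
54	9092	SART1	2	1	1	PARK7	–	–	376	–	–	–	–	–	–	6
55	9551	ATP5J2	2	2	6	0	–	–	379	true	true	–	–	–	true	6
56	10627	MYL12A	2	1	1	PARK7	–	–	385	–	–	–	–	–	true	6
57	509	ATP5C1	2	2	7	0	–	–	389	true	true	–	–	–	–	6
58	6224	RPS20	2	2	7	0	–	–	390	–	true	–	true	–	–	6
59	6137	RPL13	2	2	8	0	–	–	436	–	true	–	–	–	true	6
60	6128	RPL6	2	2	7	0	–	–	468	–	true	–	–	–	true	6
61	7203	CCT3	2	2	8	0	–	–	598	true	true	–	true	true	true	6
62	302	ANXA2	2	1	1	UCHL1	–	–	811	–	–	–	–	–	true	6
63	3185	HNRNPF	2	1	1	UCHL1	–	–	928	–	–	–	–	–	true	6
64	8363	HIST1H4J	–	–	–	0	–	–	–	–	true	–	–	–	–	6
65	7171	TPM4	3	2	3	0	–	–	12	–	–	true	–	–	–	7
66	4724	NDUFS4	3	2	3	0	–	–	44	true	–	true	–	–	–	7
67	9118	INA	2	2	6	0	–	–	82	–	–	true	–	–	–	7
68	3306	HSPA2	2	2	7	0	–	true	95	true	–	true	true	–	–	7
69	1153	CIRBP	2	2	4	0	–	–	149	–	–	true	–	true	–	7
70	8531	CSDA	2	2	7	0	–	–	167	–	–	true	true	true	–	7
71	4001	LMNB1	2	2	7	0	–	–	206	–	–	true	true	true	–	7
72	291	SLC25A4	2	2	6	0	–	–	227	true	–	true	–	–	–	7
73	811	CALR	2	2	6	0	–	–	235	true	–	true	–	–	true	7
74	6182	MRPL12	2	2	5	0	–	–	263	true	–	true	–	–	true	7
75	27339	PRPF19	2	2	7	0	–	–	275	–	–	true	true	–	–	7
76	6421	SFPQ	2	2	7	0	–	–	307	–	–	true	true	true	–	7
77	7184	HSP90B1	2	2	7	0	–	–	316	true	–	true	–	–	true	7
78	5984	RFC4	2	2	6	0	–	–	324	–	–	true	–	–	true	7
79	2521	FUS	2	2	6	0	–	–	354	–	–	true	true	true	–	7
80	4720	NDUFS2	2	2	8	0	–	–	410	–	–	true	true	true	true	7
81	6742	SSBP1	2	2	7	0	–	–	531	true	–	true	true	true	true	7
82	10642	IGF2BP1	2	2	8	0	–	–	647	–	–	true	–	–	–	7
83	3305	HSPA1L	2	2	8	0	–	true	661	true	–	true	true	true	true	7
84	708	C1QBP	2	2	7	0	–	–	661	–	–	true	true	–	true	7
85	2547	XRCC6	2	2	8	0	–	–	813	–	–	true	true	true	–	7
86	7531	YWHAE	2	2	8	0	–	–	833	true	–	true	–	–	true	7
87	8607	RUVBL1	2	2	8	0	–	–	858	–	–	true	true	–	–	7
88	4000	LMNA	2	2	8	0	–	–	871	true	–	true	true	true	true	7
89	10856	RUVBL2	2	2	8	0	–	–	960	true	–	true	true	–	–	7
90	7425	VGF	–	–	–	0	–	–	–	true	–	true	–	–	–	7
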