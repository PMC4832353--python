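ref_start	ref_end	clone	query_start	query_end	pct_identity	length	mismatches	gap_opens	evalue	bitscore	footnote
13423	13479	113H10	18171	18211	71.93	57	0	2	0.066	37.4	.
14226	14304	113H10	20773	20851	72.62	84	13	3	4.00E-04	44.6	.
19665	19697	99M22	37506	37474	90.91	33	3	0	1.00E-04	46.4	.
23323	23352	99M22	57812	57841	93.33	30	2	0	1.00E-04	46.4	A
25810	25845	99M22	73435	73400	100.00	36	0	0	1.00E-10	66.2	A
33788	33828	97L04	44884	44925	90.48	42	3	1	3.00E-07	55.4	.
34886	34928	97L04	50672	50630	90.70	43	4	0	7.00E-09	60.8	.
37687	37713	97L04	24868	24894	96.30	27	1	0	5.00E-04	44.6	.
38125	38149	97L04	70125	70101	96.00	25	1	0	0.006	41.0	.
40105	40129	97L04	90093	90069	92.00	25	2	0	0.076	37.4	sc-SOPE
42356	42403	97L04	99269	99316	89.58	48	5	0	5.00E-10	64.4	L3/TSM
42858	42923	97L04	104855	104920	81.82	66	12	0	2.00E-10	66.2	sc-UTR
46110	46141	62B24	47973	47942	90.62	32	3	0	4.00E-04	44.6	.
46525	46558	62B24	46965	46931	91.43	35	2	1	1.00E-04	46.4	.
51057	51103	62B24	72470	72424	87.23	47	6	0	2.00E-08	59.0	pTG
51964	52013	16B10	30646	30599	86.00	50	5	1	1.00E-07	57.2	pTG
52755	52844	16B10	24209	24116	82.98	94	12	3	6.00E-17	87.8	pTG
53731	53762	62B24	89286	89255	93.75	32	2	0	1.00E-05	50.0	pTG
57555	57671	16B10	50662	50779	70.25	121	29	4	6.00E-04	44.6	l'sc-UTR
66739	66764	16B10	117858	117833	92.31	26	2	0	0.026	39.2	C
68213	68243	104L14	28982	29012	90.32	31	3	0	0.002	42.8	C
68286	68311	104L14	29081	29106	92.31	26	2	0	0.023	39.2	C
69400	69423	104L14	32865	32888	95.83	24	1	0	0.023	39.2	C
69638	69686	104L14	32987	33035	86.00	50	5	2	4.00E-06	51.8	C
72901	72925	104L14	26919	26895	100.00	25	0	0	2.00E-04	46.4	tr1-tr2
86922	86977	104L14	54520	54575	87.50	56	7	0	1.00E-11	69.8	.
90692	90719	104L14	69009	69036	100.00	28	0	0	4.00E-06	51.8	D
109968	109997	97L04	107083	107054	86.67	30	4	0	0.076	37.4	E
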