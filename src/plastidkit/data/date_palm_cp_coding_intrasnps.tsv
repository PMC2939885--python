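no	gene	major	minor	major_codon	minor_codon	major_aa	minor_aa	major_n	minor_n	major_pct	minor_pct	strand	cds_pos	genome_pos	swap_vs_oil_palm
1	psbA	C	T	acC	acT	Thr	Thr	863	124	87.4	12.6	-	858	352	1
2	psbA	G	A	gGa	gAa	Gly	Glu	863	206	80.7	19.3	-	728	482	1
3	psbA	A	G	gcA	gcG	Ala	Ala	1167	296	79.8	20.2	-	564	646	1
4	psbA	T	G	cTa	cGa	Leu	Arg	1117	250	81.7	18.3	-	350	860	0
5	psbA	C	T	tcC	tcT	Ser	Ser	1061	190	84.8	15.2	-	303	907	1
6	atpF	A	G	gaA	gaG	Glu	Glu	928	132	87.5	12.5	-	282	12699	1
7	atpI	A	T	Agt	Tgt	Ser	Cys	774	93	89.3	10.7	-	559	15572	0
8	rps2	G	A	Gcg	Acg	Ala	Thr	558	62	90.0	10.0	-	475	16632	1
9	rpoC2	A	C	aaA	aaC	Lys	Asn	564	211	72.8	27.2	-	711	20742	0
10	rpoC2	C	A	caC	caA	His	Gln	988	202	83.0	17.0	-	636	20817	0
11	rpoC2	T	C	caT	caC	His	His	898	134	87.0	13.0	-	432	21021	1
12	rpoC2	A	C	Aat	Cat	Asn	His	828	101	89.1	10.9	-	352	21101	0
13	rpoC2	T	G	tTa	tGa	Leu	-	789	99	88.9	11.1	-	290	21163	0
14	rpoC2	T	C	Ttt	GtC	Phe	Val	398	94	80.9	19.1	-	240	21213	0
15	rpoC2	T	G							-	238	21215	0
16	rpoC1	A	G	aAt	aGt	Asn	Ser	624	231	73.0	27.0	-	1931	21750	1
17	rpoC1	A	C	ttA	ttC	Leu	Phe	938	235	80.0	20.0	-	1503	22178	0
18	rpoC1	A	C	ttA	ttC	Leu	Phe	702	225	75.7	24.3	-	1230	22451	0
19	rpoC1	A	G	ctA	ctG	Leu	Leu	952	223	81.0	19.0	-	1113	22568	1
20	rpoC1	G	A	gaG	gaA	Glu	Glu	762	181	80.8	19.2	-	1092	22589	1
21	rpoC1	T	C	ctT	ctC	Leu	Leu	674	231	74.5	25.5	-	885	22796	1
22	rpoC1	T	G	ttT	ttG	Phe	Leu	256	53	82.8	17.2	-	537	23144	0
23	rpoC1	A	C	Aga	Cga	Arg	Arg	529	171	75.6	24.4	-	199	24221	0
24	rpoB	T	G	tTt	tGt	Phe	Cys	661	165	80.0	20.0	-	2744	24909	0
25	rpoB	C	T	tgC	tgT	Cys	Cys	748	137	84.5	15.5	-	2601	25052	1
26	rpoB	A	C	tcA	tcC	Ser	Ser	319	114	73.7	26.3	-	2487	25166	0
27	rpoB	G	T	Gat	Tat	Asp	Tyr	963	132	87.9	12.1	-	2035	25618	0
28	psaB	T	C	gaT	gaC	Asp	Asp	789	106	88.2	11.8	-	1092	39000	1
29	psaB	G	T	ggG	ggT	Gly	Gly	874	100	89.7	10.3	-	864	39228	1
30	psaB	G	T	Gat	Tat	Asp	Tyr	868	106	89.1	10.9	-	814	39278	0
31	psaB	A	G	acA	acG	Thr	Thr	647	87	88.1	11.9	-	795	39297	1
32	psaB	C	T	agC	agT	Ser	Ser	861	109	88.8	11.2	-	720	39372	1
33	psaA	A	C	ttA	ttC	Leu	Phe	521	210	71.3	28.7	-	2118	40252	0
34	psaA	A	C	tcA	tcC	Ser	Ser	858	145	85.5	14.5	-	1800	40570	0
35	rps4	A	C	atA	atC	Ile	Ile	836	132	86.4	15.6	-	282	46306	1
36	ndhJ	T	C	ttT	ttC	Phe	Phe	407	113	78.3	21.7	-	456	49697	1
37	atpB	A	C	gtA	gtC	Val	Val	1041	257	80.2	19.8	-	696	55445	0
38	accD	G	A	gaG	gaA	Glu	Glu	708	88	88.9	11.1	+	48	59201	0
39	accD	C	T	tcC	tcT	Ser	Ser	680	94	87.9	12.1	+	276	59429	0
40	accD	C	A	Cat	Aat	His	Asn	863	108	88.9	11.1	+	403	59556	0
41	accD	T	G	Tac	Gac	Tyr	Asp	852	106	88.9	11.1	+	406	59559	0
42	accD	T	G	ttT	ttG	Phe	Leu	618	106	85.4	14.6	+	987	60140	0
43	accD	G	A	gGa	gAa	Gly	Glu	877	114	88.5	11.5	+	1097	60250	0
44	accD	C	T	tcC	tcT	Ser	Ser	848	102	89.3	10.7	+	1152	60305	0
45	accD	A	C	Aaa	Caa	Lys	Gln	354	102	77.6	22.4	+	1177	60330	0
46	cemA	G	C	gtG	gtC	Val	Val	1181	175	87.1	12.9	+	672	63407	0
47	petA	A	G	gcA	gcG	Ala	Ala	844	113	88.2	11.8	+	828	64480	0
48	psbE	G	A	ccG	ccA	Pro	Pro	951	130	88.0	12.0	-	192	66208	1
49	psbB	A	C	ttA	ttC	Leu	Phe	640	184	77.7	22.3	+	927	75429	0
50	psbT	A	C	atA	atC	Ile	Ile	695	153	82.0	18.0	+	48	76250	0
51	psbT	A	C	Aaa	Caa	Lys	Gln	233	151	60.7	39.3	+	100	76302	0
52	psbH	A	G	acA	acG	Thr	Thr	782	115	87.2	12.8	+	120	76734	0
53	psbH	G	A	ttG	ttA	Leu	Leu	651	89	88.0	12.0	+	174	76788	0
54	psbH	T	G	atT	atG	Ile	Met	468	85	84.6	15.4	+	180	76794	0
55	psbH	T	G	Tat	Gat	Tyr	Asp	469	85	84.7	15.3	+	181	76795	0
56	petB	T	A	aTa	aAa	Ile	Lys	715	108	86.9	13.1	+	101	77843	0
57	petB	T	G	Tat	Gat	Tyr	Asp	520	123	80.9	19.1	+	106	77848	0
58	petB	T	G	Tac	Gac	Tyr	Asp	493	152	76.4	23.6	+	175	77917	0
59	petB	A	C	gtA	gtC	Val	Val	576	219	72.5	27.5	+	450	78192	0
60	rps11	A	C	Att	Ctt	Ile	Leu	1007	120	89.4	10.6	-	118	81436	0
61	ycf2	T	G	ttT	ttG	Phe	Leu	917	121	88.3	11.7	+	3765	92696	0
62	ndhA	T	G	tTa	tGa	Leu	-	793	100	88.8	11.2	-	1010	122904	0
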