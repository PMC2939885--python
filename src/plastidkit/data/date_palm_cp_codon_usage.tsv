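amino_acid	codon	count	rscu_printed	trna
Phe	UUU	836	1.29
Phe	UUC	462	0.71	trnF-GAA
Leu	UUA	734	1.89	trnL-UAA
Leu	UUG	500	1.29	trnL-CAA
Ser	UCU	498	1.69
Ser	UCC	289	0.98	trnS-GGA
Ser	UCA	371	1.26	trnS-UGA
Ser	UCG	162	0.55
Tyr	UAU	700	1.6
Tyr	UAC	177	0.4	trnY-GUA
Ter	UAA	37	0
Ter	UAG	22	0
Cys	UGU	207	1.53	trnC-GCA
Cys	UGC	64	0.47
Ter	UGA	20	0
Trp	UGG	392	1	trnW-CCA
Leu	CUU	473	1.22
Leu	CUC	162	0.42
Leu	CUA	314	0.81	trnL-UAG
Leu	CUG	150	0.39
Pro	CCU	367	1.57
Pro	CCC	185	0.79
Pro	CCA	275	1.18	trnP-UGG
Pro	CCG	107	0.46
His	CAU	423	1.54
His	CAC	127	0.46	trnH-GUG
Gln	CAA	608	1.5	trnQ-UUG
Gln	CAG	200	0.5
Arg	CGU	322	1.39	trnR-ACG
Arg	CGC	78	0.34
Arg	CGA	307	1.32
Arg	CGG	106	0.46
Ile	AUU	959	1.44
Ile	AUC	415	0.62	trnI-GAU
Ile	AUA	627	0.94
Met	AUG	545	1	trn(f)M-CAU
Thr	ACU	465	1.56
Thr	ACC	223	0.75	trnT-GGU
Thr	ACA	382	1.28	trnT-UGU
Thr	ACG	125	0.42
Asn	AAU	857	1.59
Asn	AAC	223	0.41	trnN-GUU
Lys	AAA	884	1.5	trnK-UUU
Lys	AAG	294	0.5
Ser	AGU	361	1.23
Ser	AGC	84	0.29	trnS-GCU
Arg	AGA	445	1.92	trnR-UCU
Arg	AGG	135	0.58
Val	GUU	470	1.44
Val	GUC	162	0.5	trnV-GAC
Val	GUA	496	1.52	trnV-UAC
Val	GUG	181	0.55
Ala	GCU	559	1.83
Ala	GCC	188	0.62
Ala	GCA	347	1.14	trnA-UGC
Ala	GCG	127	0.42
Asp	GAU	741	1.6
Asp	GAC	184	0.4	trnD-GUC
Glu	GAA	935	1.53	trnE-UUC
Glu	GAG	290	0.47
Gly	GGU	550	1.4
Gly	GGC	137	0.35	trnG-GCC
Gly	GGA	633	1.61	trnG-UCC
Gly	GGG	251	0.64
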