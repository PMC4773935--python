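site	observed	1A	1B	2	3	4	5	6	7	8	9
Head and neck	324	279	288	287	306	246	221	292	298	291	335
Oesophagus	168	159	160	154	181	170	182	146	166	155	217
Stomach	293	296	294	355	281	269	276	431	296	238	297
Colon-rectum	1948	1947	1882	1895	1834	1668	1994	2083	1797	1617	1428
Liver	120	105	98	94	100	99	112	91	94	113	193
Gallbladder	73	76	64	67	43	25	28	68	71	60	89
Pancreas	332	377	385	352	376	309	367	343	355	281	329
Larynx	97	89	82	107	113	112	119	110	113	83	104
Lung	1561	1554	1617	1579	1494	1338	1439	1654	1549	1357	1357
Melanoma of skin	773	616	672	592	669	726	815	503	646	741	578
Prostate	4533	5414	5487	4302	4165	3897	8741	4397	4286	3805	3815
Testis	288	299	303	272	229	230	172	282	256	232	185
Kidney	484	463	452	407	404	296	418	405	406	428	400
Bladder	938	1045	1050	1000	1071	843	1078	1060	956	809	924
Brain and CNS	518	628	625	530	562	368	563	527	515	452	412
Thyroid	77	80	87	67	38	38	70	61	71	65	87
Hodgkin lymphoma	73	94	73	76	54	47	45	63	80	62	63
Non-Hodgkin lymphoma	499	483	485	451	426	391	444	420	473	441	455
Multiple myeloma	218	210	211	202	186	169	216	187	209	194	162
Leukaemia	363	339	344	336	310	292	403	290	361	368	313
Other and unspecified	827	858	867	829	662	569	759	826	845	752	839
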