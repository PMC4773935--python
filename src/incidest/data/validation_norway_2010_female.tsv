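site	observed	1A	1B	2	3	4	5	6	7	8	9
Head and neck	188	174	187	163	165	136	157	155	174	192	185
Oesophagus	58	62	56	56	56	56	61	53	64	54	85
Stomach	196	201	218	230	210	188	209	280	200	151	197
Colon-rectum	1894	1939	1947	1856	1732	1647	2217	1961	1781	1671	1309
Liver	73	49	59	49	74	65	86	54	48	63	94
Gallbladder	84	83	85	80	44	23	34	72	79	75	96
Pancreas	358	363	369	355	361	286	367	342	348	303	331
Larynx	18	10	14	15	17	18	19	14	18	19	21
Lung	1210	1197	1328	1042	1172	1026	1118	965	1095	1173	1171
Melanoma of skin	797	698	707	630	936	1068	1591	557	675	793	646
Breast	2891	3059	2896	2958	2672	2550	4540	2818	3062	2772	3651
Cervix uteri	307	285	296	310	282	234	338	330	312	286	250
Corpus uteri	744	801	763	715	639	632	691	721	740	721	599
Ovary	479	432	462	489	451	445	559	477	509	457	392
Kidney	246	269	272	237	215	140	263	232	229	216	243
Bladder	359	378	326	349	351	321	438	353	347	329	306
Brain and CNS	629	903	858	688	663	407	788	672	672	542	459
Thyroid	206	184	176	163	189	181	236	177	152	206	242
Hodgkin lymphoma	57	56	54	51	25	23	39	56	50	54	54
Non-Hodgkin lymphoma	412	398	390	374	292	274	436	371	369	381	385
Multiple myeloma	159	164	164	162	126	130	207	151	171	151	129
Leukaemia	272	260	253	248	216	197	307	223	265	276	218
Other and unspecified	829	910	857	855	762	726	921	807	886	767	876
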