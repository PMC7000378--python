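region_id	abbreviation	name	day1_coef	day2_coef
72	CAU	R Caudate (CAU)	0.054	0.010
73	PUT	L Putamen (PUT)	-0.375	0.065
74	PUT	R Putamen (PUT)	-0.449	0.010
63	SMG	L Supramarginal gyrus (SMG)	0.294	-0.008
58	POST	R Postcentral gyrus (POST)	-0.379	-0.161
40	PHIP	R Parahippocampus (PHIP)	0.092	0.015
15	F3O	L Inferior frontal gyrus, orbital (F3O)	0.142	0.214
86	T2	R Middle temporal gyrus (T2)	-0.106	-0.153
83	T1P	L Temporal pole; superior temporal gyrus (T1P)	-0.128	-0.427
104		R Cerebellum 8	0.115	-0.028
3	F1	L Superior frontal gyrus, dorsolateral (F1)	-0.117
4	F1	R Superior frontal gyrus, dorsolateral (F1)	0.107
24	F1M	R Superior frontal gyrus, medial (F1M)	0.303
10	F2O	R Middle frontal gyrus, orbital (F2O)	-0.262
28	GR	R Gyrus rectus (GR)	-0.081
9	F2O	L Middle frontal gyrus, orbital (F2O)	0.193
88	T2P	R Temporal pole; middle temporal gyrus (T2P)	0.000
64	SMG	R Supramarginal gyrus (SMG)	0.206
97		L Cerebellum 4 5	0.340
112		R Vermis 6	-0.374
99		L Cerebellum 6	-0.278
20	SMA	R Supplementary motor area (SMA)	-0.145
69	PCL	L Paracentral lobule (PCL)	-0.176
18	RO	R Rolandic operculum (RO)	0.534
46	Q	R Cuneus (Q)	0.566
48	LING	R Lingual gyrus (LING)	-0.292
49	O1	L Superior occipital lobe (O1)	0.290
52	O2	R Middle occipital lobe (O2)	-0.262
56	FUSI	R Fusiform gyrus (FUSI)	0.269
75	PAL	L Pallidum (PAL)		-0.172
76	PAL	R Pallidum (PAL)		-0.062
43	V1	L Calcarine fissure and surrounding cortex (V1)		-0.134
44	V1	R Calcarine fissure and surrounding cortex (V1)		0.122
51	O2	L Middle occipital lobe (O2)		0.203
53	O3	L Inferior occipital lobe (O3)		-0.209
82	T1	R Superior temporal gyrus (T1)		0.252
12	F3OP	R Inferior frontal gyrus, opercular (F3OP)		0.139
14	F3T	R Inferior frontal gyrus, triangular (F3T)		-0.148
6	F1O	R Superior frontal gyrus, orbital (F1O)		-0.039
26	F1MO	R Superior frontal gyrus, medial orbital (F1MO)		-0.178
67	PQ	L Precuneus (PQ)		-0.172
68	PQ	R Precuneus (PQ)		0.107
85	T2	L Middle temporal gyrus (T2)		0.091
17	RO	L Rolandic operculum (RO)		0.542
57	POST	L Postcentral gyrus (POST)		0.071
92		R Cerebellum crus 1		0.086
105		L Cerebellum 9		0.095
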