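# Cohort fixture: 115 Lynch-like syndrome cases.
# 49 cases transcribed from the published cohort table (variant inventories,
# epimutation flags, printed final labels kept for traceability); the
# remaining 66 cases of the cohort are not itemized in the main text and are
# encoded as plain LLS cases with no annotated variants.  Case 44's variant
# is detailed only in the paper supplement and is encoded as one unspecified
# other-gene VUS.  mmr_variants entries: gene:cdna:initial_class:final_class.
case_id	mmr_variants	other_variants	epimutation	mutyh_biallelic	printed_label
1			0	0	LLS
2			0	0	LLS
3			0	0	LLS
4			0	0	LLS
5	MSH6:c.2092C>G:3:3		0	0	LLS (MMR VUS carrier)
6			0	0	LLS
7			1	0	LS (MLH1 epimutation carrier)
8			0	0	LLS
9			0	0	LLS
10		EPCAM:vus	0	0	LLS (VUS carrier)
11			0	0	LLS
12			0	0	LLS
13	MLH1:c.-574T>C:3:3		0	0	LLS (MMR VUS carrier)
14			0	0	LLS
15			0	0	LLS
16			0	0	LLS
17			0	0	LLS
18			0	0	LLS
19			0	0	LLS
20			0	0	LLS
21			0	0	LLS
22			0	0	LLS
23			0	0	LLS
24			0	0	LLS
25			0	0	LLS
26			0	0	LLS
27			0	0	LLS
28			0	0	LLS
29		POLD1:vus	0	0	LLS (VUS carrier)
30		APC:vus	0	0	LLS (VUS carrier)
31			0	0	LLS
32			0	0	LLS
33	MLH1:c.676C>T:5:5		0	0	LS
34			0	0	LLS
35	MLH1:c.25C>T:3:3	APC:pathogenic	0	0	FAP (MMR VUS carrier)
36			0	0	LLS
37			0	0	LLS
38			0	0	LLS
39	MSH2:c.1787A>G:3:3	FAN1:vus	0	0	LLS (MMR VUS carrier)
40			0	0	LLS
41			0	0	LLS
42			0	0	LLS
43			0	0	LLS
44		unspecified:vus	0	0	LLS (VUS carrier)
45			0	0	LLS
46			0	0	LLS
47			0	0	LLS
48			0	0	LLS
49			0	0	LLS
50			0	0	LLS
51			0	0	LLS
52			0	0	LLS
53			0	0	LLS
54			0	0	LLS
55		PMS1:vus	0	0	LLS (VUS carrier)
56			0	0	LLS
57	MSH2:exon8dup:3:5		0	0	LS
58	MSH2:c.2045C>G:3:3	EXO1:vus	0	0	LLS (MMR VUS carrier)
59		APC:vus	0	0	LLS (VUS carrier)
60			0	0	LLS
61			0	0	LLS
62		MSH3:vus	0	0	LLS (VUS carrier)
63	MSH2:c.2702A>T:3:3		0	0	LLS (MMR VUS carrier)
64			0	0	LLS
65		MUTYH:pathogenic	0	0	LLS (monoallelic MUTYH carrier)
66			0	0	LLS
67	MSH6:c.1153_1155del:3:4		0	0	LS
68			0	0	LLS
69			0	0	LLS
70	MSH6:c.1618_1620del:3:5		0	0	LS
71			0	0	LLS
72	MSH6:c.1450G>A:3:3		0	0	LLS (MMR VUS carrier)
73	MSH6:c.3296T>A:3:3		0	0	LLS (MMR VUS carrier)
74		MSH3:vus;MSH3:vus	0	0	LLS (VUS carrier)
75	MSH6:c.1618_1620del:3:5		0	0	LS
76			0	0	LLS
77	MSH6:c.3226C>T:3:4		0	0	LS
78			0	0	LLS
79			0	0	LLS
80			0	0	LLS
81		BUB1:vus	0	0	LLS (VUS carrier)
82	MSH6:c.3150_3161dup:3:5		0	0	LS
83			0	0	LLS
84			0	0	LLS
85	PMS2:c.1320A>G:3:3	MSH3:vus	0	0	LLS (MMR VUS carrier)
86			0	0	LLS
87			0	0	LLS
88			0	0	LLS
89			0	0	LLS
90			0	0	LLS
91			0	0	LLS
92	MSH6:c.2219T>A:5:5		0	0	LS
93			0	0	LLS
94			0	0	LLS
95			0	0	LLS
96		APC:vus	0	0	LLS (VUS carrier)
97			0	0	LLS
98	MSH2:c.2802G>A:3:3		0	0	LLS (MMR VUS carrier)
99			0	0	LLS
100			0	0	LLS
101			0	0	LLS
102			0	0	LLS
103			0	0	LLS
104			0	0	LLS
105			0	0	LLS
106			0	0	LLS
107			0	0	LLS
108			0	0	LLS
109			0	0	LLS
110			0	0	LLS
111			0	0	LLS
112			0	0	LLS
113			0	0	LLS
114			0	0	LLS
115			0	0	LLS
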