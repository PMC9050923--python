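compound_id	r1_token	r2_token	MDA-MB231	SKBR-3	MCF-7
1	Ph	Ph	87	81	90
2	Ph	2-FC6H4	82	83	99
3	Ph	4-FC6H4	81	84	100
4	Ph	2-ClC6H4	72	88	81
5	Ph	4-ClC6H4	65	94	100
6	Ph	4-BrC6H4	65	97	100
7	Ph	4-MeC6H4	98	87	87
8	Ph	2-MeOC6H4	78	97	91
9	Ph	4-MeOC6H4	98	96	84
10	Ph	4-CF3OC6H4	96	86	92
11	Ph	4-iPrC6H4	99	86	99
12	Ph	3-Pyridyl	59	78	87
13	3-FC6H4	Ph	100	100	89
14	3-FC6H4	4-FC6H4	50	100	78
15	3-FC6H4	4-ClC6H4	100	100	89
16	3-FC6H4	4-BrC6H4	43	89	80
17	3-FC6H4	4-MeC6H4	29	90	71
18	3-FC6H4	4-MeOC6H4	46	74	76
19	3-FC6H4	4-CF3OC6H4	50	100	76
20	3-FC6H4	4-iPrC6H4	100	100	92
21	4-FC6H4	Ph	83	94	100
22	4-FC6H4	2-FC6H4	83	85	100
23	4-FC6H4	4-FC6H4	81	100	93
24	4-FC6H4	2-ClC6H4	75	75	91
25	4-FC6H4	3-ClC6H4	73	88	95
26	4-FC6H4	4-ClC6H4	67	98	87
27	4-FC6H4	4-BrC6H4	96	100	94
28	4-FC6H4	4-MeC6H4	99	90	88
29	4-FC6H4	2-MeOC6H4	60	81	96
30	4-FC6H4	4-MeOC6H4	74	90	92
31	4-FC6H4	4-CF3OC6H4	88	92	87
32	4-FC6H4	4-iPrC6H4	94	100	84
33	4-FC6H4	3-Pyridyl	74	87	85
34	4-ClC6H4	Ph	81	100	100
35	4-ClC6H4	2-FC6H4	82	99	93
36	4-ClC6H4	4-FC6H4	49	98	100
37	4-ClC6H4	2-ClC6H4	99	89	99
38	4-ClC6H4	3-ClC6H4	99	92	84
39	4-ClC6H4	4-ClC6H4	97	100	100
40	4-ClC6H4	4-BrC6H4	80	100	92
41	4-ClC6H4	2-MeOC6H4	83	89	100
42	4-ClC6H4	4-MeOC6H4	61	90	85
43	4-ClC6H4	4-CF3OC6H4	93	83	100
44	4-ClC6H4	4-iPrC6H4	100	97	96
45	4-ClC6H4	3-Pyridyl	99	74	89
46	4-BrC6H4	2-FC6H4	75	91	100
47	4-BrC6H4	4-FC6H4	58	98	100
48	4-BrC6H4	2-ClC6H4	90	93	100
49	4-BrC6H4	4-ClC6H4	96	100	100
50	4-BrC6H4	4-MeC6H4	55	93	88
51	4-BrC6H4	2-MeOC6H4	88	89	96
52	4-BrC6H4	4-MeOC6H4	56	91	100
53	3-MeC6H4	4-FC6H4	100	100	78
54	3-MeC6H4	4-ClC6H4	100	93	76
55	3-MeC6H4	4-BrC6H4	83	96	75
56	3-MeC6H4	4-MeC6H4	12	62	67
57	3-MeC6H4	4-MeOC6H4	91	90	75
58	3-MeC6H4	4-CF3OC6H4	50	100	73
59	3-MeC6H4	4-iPrC6H4	87	93	76
60	4-MeC6H4	Ph	84	100	100
61	4-MeC6H4	2-FC6H4	50	79	73
62	4-MeC6H4	4-FC6H4	48	78	100
63	4-MeC6H4	4-BrC6H4	87	100	93
64	4-MeC6H4	4-MeC6H4	59	92	86
65	4-MeC6H4	2-MeOC6H4	97	88	87
66	4-MeC6H4	4-MeOC6H4	83	89	100
67	4-MeC6H4	4-CF3OC6H4	92	84	93
68	4-MeC6H4	4-iPrC6H4	76	91	100
69	4-MeC6H4	3-Pyridyl	74	79	88
70	4-MeOC6H4	2-FC6H4	9	46	63
71	4-MeOC6H4	4-MeOC6H4	56	93	95
72	4-MeOC6H4	4-FC6H4	68	100	100
73	4-MeOC6H4	2-ClC6H4	10	47	84
74	4-MeOC6H4	3-ClC6H4	22	45	86
75	4-MeOC6H4	4-ClC6H4	99	100	100
76	4-MeOC6H4	4-BrC6H4	96	100	91
77	4-MeOC6H4	3-MeC6H4	22	40	79
78	4-MeOC6H4	2-MeOC6H4	50	66	57
79	4-MeOC6H4	4-CF3OC6H4	74	84	95
80	4-MeOC6H4	4-iPrC6H4	92	86	100
81	4-MeOC6H4	3-Pyridyl	46	77	91
82	4-CF3C6H4	Ph	55	97	96
83	4-CF3C6H4	2-FC6H4	55	71	93
84	4-CF3C6H4	4-FC6H4	95	98	100
85	4-CF3C6H4	4-ClC6H4	90	77	99
86	4-CF3C6H4	4-MeC6H4	54	95	83
87	4-CF3C6H4	2-MeOC6H4	63	85	100
88	4-CF3C6H4	4-MeOC6H4	81	86	100
89	4-CF3OC6H4	Ph	59	90	95
90	4-CF3OC6H4	2-FC6H4	60	80	90
91	4-CF3OC6H4	4-FC6H4	53	86	100
92	4-CF3OC6H4	2-ClC6H4	74	86	96
93	4-CF3OC6H4	4-BrC6H4	83	96	90
94	4-CF3OC6H4	4-MeC6H4	79	87	97
95	4-CF3OC6H4	2-MeOC6H4	46	81	88
96	4-CF3OC6H4	4-MeOC6H4	69	88	87
97	4-CF3OC6H4	4-CF3OC6H4	92	80	100
98	4-CF3OC6H4	4-iPrC6H4	100	90	95
99	4-CF3OC6H4	3-Pyridyl	33	81	85
100	4-Me2NC6H4	Ph	21	61	80
101	4-Me2NC6H4	2-FC6H4	28	51	88
102	4-Me2NC6H4	4-FC6H4	32	88	90
103	4-Me2NC6H4	2-MeOC6H4	28	48	88
104	4-Me2NC6H4	4-iPrC6H4	70	87	100
105	4-tBuC6H4	Ph	74	100	96
106	4-tBuC6H4	4-FC6H4	97	84	88
107	4-tBuC6H4	4-ClC6H4	100	92	98
108	4-tBuC6H4	4-BrC6H4	59	98	99
109	4-tBuC6H4	4-MeOC6H4	91	85	93
110	4-BnOC6H4	Ph	51	75	100
111	4-BnOC6H4	4-FC6H4	69	84	89
112	4-BnOC6H4	4-BrC6H4	82	93	97
113	4-BnOC6H4	4-MeC6H4	82	94	100
114	4-BnOC6H4	4-CF3OC6H4	71	87	100
115	2-Thienyl	Ph	100	87	91
116	2-Thienyl	2-FC6H4	98	78	90
117	2-Thienyl	4-FC6H4	100	86	92
118	2-Thienyl	2-ClC6H4	100	78	91
119	2-Thienyl	4-ClC6H4	100	89	98
120	2-Thienyl	4-BrC6H4	46	87	88
121	2-Thienyl	4-MeC6H4	49	95	97
122	2-Thienyl	2-MeOC6H4	78	97	91
123	2-Thienyl	4-MeOC6H4	93	88	80
124	2-Thienyl	4-CF3OC6H4	100	86	85
125	2-Thienyl	4-iPrC6H4	100	86	89
126	2-Thienyl	3-Pyridyl	100	91	86
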