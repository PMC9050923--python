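compound_id	cell_line	gi50_uM	sem_uM
14	MDA-MB231	9.21	0.38
14	SKBR-3	>20
14	MCF-7	>20
14	MCF-10A	>25
16	MDA-MB231	13.13	0.91
16	SKBR-3	17.16	1.07
16	MCF-7	>20
16	MCF-10A	>25
17	MDA-MB231	3.96	0.17
17	SKBR-3	>20
17	MCF-7	>20
17	MCF-10A	>25
18	MDA-MB231	6.18	0.43
18	SKBR-3	16.63	1.38
18	MCF-7	>20
18	MCF-10A	>25
19	MDA-MB231	8.56	0.59
19	SKBR-3	>20
19	MCF-7	18.22	1.28
19	MCF-10A	>25
36	MDA-MB231	14.14	1.52
36	SKBR-3	19.40	2.39
36	MCF-7	>20
36	MCF-10A	>25
56	MDA-MB231	0.17	0.02
56	SKBR-3	1.26	0.18
56	MCF-7	>20
56	MCF-10A	>25
58	MDA-MB231	15.24	1.01
58	SKBR-3	>20
58	MCF-7	>20
58	MCF-10A	>25
61	MDA-MB231	12.25	1.15
61	SKBR-3	>20
61	MCF-7	>20
61	MCF-10A	>25
62	MDA-MB231	10.68	0.73
62	SKBR-3	>20
62	MCF-7	20.15	1.95
62	MCF-10A	>25
70	MDA-MB231	0.32	0.04
70	SKBR-3	>20
70	MCF-7	>20
70	MCF-10A	>25
73	MDA-MB231	0.23	0.03
73	SKBR-3	1.10	0.01
73	MCF-7	>20
73	MCF-10A	>25
74	MDA-MB231	1.33	0.17
74	SKBR-3	0.18	0.04
74	MCF-7	18.30	1.11
74	MCF-10A	>25
77	MDA-MB231	0.95	0.04
77	SKBR-3	3.38	0.36
77	MCF-7	>20
77	MCF-10A	>25
78	MDA-MB231	13.25	0.93
78	SKBR-3	2.15	0.12
78	MCF-7	>20
78	MCF-10A	>25
81	MDA-MB231	14.01	1.33
81	SKBR-3	15.58	1.06
81	MCF-7	>20
81	MCF-10A	>25
95	MDA-MB231	12.77	0.76
95	SKBR-3	>20
95	MCF-7	>20
95	MCF-10A	>25
99	MDA-MB231	11.52	1.51
99	SKBR-3	>20
99	MCF-7	>20
99	MCF-10A	>25
100	MDA-MB231	0.36	0.07
100	SKBR-3	4.19	0.37
100	MCF-7	>20
100	MCF-10A	>25
101	MDA-MB231	0.06	0.001
101	SKBR-3	0.29	0.04
101	MCF-7	>20
101	MCF-10A	>25
102	MDA-MB231	7.20	0.94
102	SKBR-3	>20
102	MCF-7	>20
102	MCF-10A	>25
103	MDA-MB231	4.17	0.33
103	SKBR-3	3.63	0.23
103	MCF-7	>20
103	MCF-10A	>25
110	MDA-MB231	13.44	1.18
110	SKBR-3	>20
110	MCF-7	>20
110	MCF-10A	>25
120	MDA-MB231	11.73	1.39
120	SKBR-3	>20
120	MCF-7	>20
120	MCF-10A	>25
121	MDA-MB231	13.88	1.74
121	SKBR-3	>20
121	MCF-7	>20
121	MCF-10A	>25
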