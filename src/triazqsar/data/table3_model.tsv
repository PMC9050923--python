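# Published model table: experimental pGI50, model-predicted pGI50, printed residual.
# printed_id is the identifier as printed; compound_id is the default reading used
# by this package. The row printed as "71" carries the experimental pGI50 of the
# potency-table entry for compound 81 (GI50 14.01 uM -> 4.85), and 81 is otherwise
# absent here, so the default mapping reads that row as compound 81 (flagged below).
printed_id	compound_id	experimental_pgi50	predicted_pgi50	residual_printed	split	id_remapped
14	14	5.04	5.33	-0.30	train	0
16	16	4.88	4.90	-0.01	train	0
17	17	5.40	5.26	0.15	train	0
18	18	5.21	5.46	-0.25	train	0
19	19	5.07	5.01	0.06	train	0
36	36	4.85	5.04	-0.19	train	0
56	56	6.77	6.31	0.46	train	0
58	58	4.82	5.23	-0.41	test	0
61	61	4.91	5.40	-0.49	train	0
62	62	4.97	4.89	0.08	train	0
70	70	6.49	5.85	0.64	train	0
73	73	6.64	6.10	0.54	test	0
74	74	5.88	6.16	-0.29	train	0
77	77	6.02	6.03	-0.01	train	0
78	78	4.88	5.78	-0.90	test	0
71	81	4.85	5.29	-0.43	train	1
95	95	4.89	5.16	-0.27	train	0
99	99	4.94	4.28	0.66	test	0
100	100	6.44	6.27	0.17	train	0
101	101	7.22	6.55	0.67	test	0
102	102	5.14	5.04	0.10	train	0
103	103	5.38	5.29	0.09	train	0
110	110	4.87	5.07	-0.20	train	0
120	120	4.93	4.46	0.47	test	0
121	121	4.86	4.82	0.04	train	0
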