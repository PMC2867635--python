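chrom	up_A	up_B	up_C	up_D	down_A	down_B	down_C	down_D	n_transcripts
1	55	100	121	122	161	227	209	125	4046
2	64	101	117	94	119	148	115	73	2811
3	39	58	68	46	106	132	92	79	2293
4	44	65	71	53	83	114	86	73	1674
5	37	57	61	46	74	91	69	55	1978
6	54	81	78	58	61	85	114	50	2200
7	73	74	82	76	65	84	59	56	2090
8	44	69	83	57	45	74	38	42	1536
9	28	43	43	50	73	94	82	45	1624
10	32	48	42	57	62	95	66	51	1641
11	55	68	98	55	94	116	108	64	2178
12	49	70	77	54	84	91	90	65	2075
13	24	41	40	93	9	14	4	2	775
14	22	42	40	17	72	68	61	49	1301
15	32	39	47	32	67	77	66	55	1273
16	38	69	51	34	89	75	88	62	1706
17	41	65	57	33	91	107	114	92	2226
18	8	13	20	7	32	43	33	33	665
19	35	66	57	63	91	105	98	61	2338
20	58	118	73	58	34	42	32	28	1055
21	10	17	9	12	16	16	22	9	482
22	15	18	14	13	58	68	55	47	929
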