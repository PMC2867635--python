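chrom	up_A	up_B	up_C	up_D	down_A	down_B	down_C	down_D	n_probes
1	11	18	16	6	17	19	29	17	96
2	0	1	0	0	8	7	6	7	38
3	3	6	0	2	6	5	8	5	58
4	5	4	2	5	5	5	3	4	51
5	4	3	2	0	9	12	8	8	44
6	0	0	0	0	6	6	5	5	31
7	16	17	15	11	2	2	6	2	64
8	0	0	0	0	5	10	5	2	38
9	4	6	9	7	10	6	3	8	43
10	NA	2	1	NA	NA	0	0	NA	38
11	4	2	4	2	8	9	4	8	37
12	1	2	4	NA	0	0	2	NA	45
13	16	17	17	17	0	0	2	0	32
14	8	16	8	1	5	1	4	11	148
15	1	4	4	8	0	4	0	0	34
16	0	4	0	0	2	6	4	2	22
17	3	4	5	3	10	16	6	8	69
18	0	0	0	0	3	3	3	3	8
19	3	0	7	3	8	9	4	6	170
20	3	3	1	3	0	0	0	0	23
21	2	3	2	0	3	3	0	5	12
22	3	3	2	3	0	0	0	0	24
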