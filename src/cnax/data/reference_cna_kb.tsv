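chrom	gain_A	gain_B	gain_C	gain_D	loss_A	loss_B	loss_C	loss_D	chrom_kb
1	0	0	0	195	0	0	37946	0	247179
2	0	0	2512	0	0	0	0	0	242690
3	0	0	0	0	0	0	1298	0	199288
4	0	0	0	0	0	0	182616	0	191121
5	0	0	0	0	0	1219	25902	0	180617
6	0	224	0	0	0	0	0	0	170734
7	56564	0	4919	77519	0	0	0	0	158781
8	678	0	104396	80270	0	0	0	31707	146251
9	0	0	0	2999	0	0	0	0	140129
10	0	0	0	0	0	0	824	0	135254
11	0	0	496	25	0	0	0	0	133951
12	0	0	0	0	0	0	0	0	132278
13	3440	8393	78167	95475	0	0	0	0	114077
14	0	0	0	0	0	0	0	3261	106330
15	0	0	0	83	0	0	0	1199	100169
16	0	0	5288	0	0	128	0	0	88652
17	0	0	0	0	0	0	975	21956	78623
18	0	0	0	0	0	58430	75913	75714	76083
19	0	0	0	0	0	0	0	0	63784
20	62345	39471	45970	42083	0	0	0	0	62364
21	0	0	0	0	0	0	21063	19817	46892
22	0	0	0	0	0	0	0	0	49525
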