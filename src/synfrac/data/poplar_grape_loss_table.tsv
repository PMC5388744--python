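chromosome	genes	paralog1_lost	paralog2_lost	both_lost	diff
1	1327	0.58	0.63	0.55	0.05
2	1237	0.73	0.7	0.64	0.03
3	1000	0.61	0.63	0.56	0.02
4	1638	0.66	0.71	0.63	0.05
5	1748	0.71	0.68	0.63	0.03
6	1779	0.75	0.62	0.68	0.13
7	1409	0.65	0.7	0.56	0.05
8	1867	0.65	0.69	0.59	0.04
9	1221	0.78	0.78	0.73	0
10	632	0.65	0.7	0.67	0.05
11	1107	0.66	0.74	0.62	0.08
12	1481	0.79	0.71	0.68	0.08
13	1329	0.69	0.67	0.65	0.02
14	1729	0.72	0.73	0.67	0.01
15	561	0.75	0.69	0.68	0.06
16	647	0.58	0.63	0.55	0.05
17	1168	0.73	0.7	0.64	0.03
18	1886	0.61	0.63	0.56	0.02
19	1135	0.66	0.71	0.63	0.05
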