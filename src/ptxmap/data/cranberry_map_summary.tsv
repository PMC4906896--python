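# Per-LG summary of the published high-density cranberry (Vaccinium
# macrocarpon) pseudo-testcross linkage map: the integrated map (I) and the
# two parental bin maps (P1 = maternal, P2 = paternal), 12 linkage groups.
# length_* in cM; markers_* are mapped marker counts; bins_* are cosegregation
# bins; avg_gap_* in cM as printed. Column sums reproduce the published totals
# (I: 1112.1 cM / 4849 markers; P1: 1321.1 cM / 1728; P2: 1136.7 cM / 2021).
lg	length_i	length_p1	length_p2	markers_i	markers_p1	markers_p2	bins_p1	bins_p2	avg_gap_p1	avg_gap_p2
1	107.1	138.2	123.0	542	198	220	73	77	1.9	1.6
2	95.8	113.8	95.2	413	192	134	60	49	1.9	1.9
3	100.2	120.8	90.6	357	142	154	50	56	2.4	1.6
4	88.5	115.6	91.2	354	138	172	55	61	2.1	1.5
5	103.8	74.0	96.1	301	29	244	13	69	5.7	1.4
6	97.9	131.8	91.4	421	142	157	53	59	2.5	1.5
7	95.2	116.0	88.6	335	136	110	54	40	2.1	2.2
8	96.7	98.0	78.0	302	104	111	33	46	3.0	1.7
9	78.3	112.8	99.1	473	180	167	48	57	2.3	1.7
10	78.7	85.3	81.4	372	122	152	47	38	1.8	2.1
11	86.0	95.5	103.1	526	162	229	54	66	1.8	1.6
12	83.9	119.3	99.0	453	183	171	52	53	2.3	1.9
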