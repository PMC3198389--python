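clone	E31	T77	K139	G187	V298
1	aag	aag	aaa	aat	aat
2	aag	aat	aag	aag	aat
3	aat	acg	aag	aag	aat
4	aat	acg	aag	aag	aat
5	acg	act	aat	acg	act
6	acg	agt	acg	acg	act
7	acg	agt	acg	act	agt
8	acg	agt	agg	act	atg
9	acg	atg	agg	act	att
10	acg	att	agg	act	cag
11	acg	cag	agg	agg	cag
12	act	cag	agt	agt	cat
13	atg	cat	agt	agt	cat
14	cat	cat	agt	atg	ccg
15	ccg	ccg	agt	att	cct
16	ccg	ccg	atg	cag	cct
17	ccg	ccg	att	cag	cct
18	ccg	cgg	att	cag	ctg
19	ccg	cgg	cag	cat	ctg
20	cct	ctg	cag	ccg	ctt
21	cct	ctg	ccg	cct	ctt
22	cct	ctg	ccg	cgg	gag
23	cct	ctt	ccg	cgt	gag
24	cct	gat	cct	ctg	gag
25	cct	gcg	ctg	ctg	gag
26	cct	gcg	ctt	ctg	gat
27	cgg	gcg	gag	ctt	gcg
28	ctg	gcg	gag	gag	gct
29	ctg	gct	gtg	gag	ggg
30	ctg	ggg	gcg	gat	ggg
31	gag	ggt	gcg	gat	ggt
32	gag	ggt	gcg	gct	ggt
33	gat	gtg	gct	gct	gtg
34	gat	gtg	gct	ggc	gtg
35	gcg	gtt	ggg	ggt	gtt
36	gct	tag	tat	ggt	tag
37	gtt	tag	tat	gtg	tat
38	tag	tat	tcg	gtt	tcg
39	tat	tat	tcg	tct	tct
40	tat	tcg	tcg	tgg	tgg
41	tat	tcg	tcg	tgg	tgg
42	tat	tcg	tct	ttg	tgt
43	tcg	tcg	tct	ttg	ttg
44	tcg	tgg	tgt	ttg	ttg
45	tct	ttg	ttg	ttg	ttt
46	tct	ttg	ttg	ttg	ttt
47	tgg	ttt	ttt	ttg	ttt
48	ttg	ttt	ttt	ttt	ttt
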