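# Curated starter set of common functional groups.
# Columns: index, name, smarts, smiles (optional), kind.
index	name	smarts	smiles	kind
0	hydroxyl	[OX2H]	O	functional_group
1	phenol	[OX2H][c]		functional_group
2	primary-alcohol	[CH2X4][OX2H]	CO	functional_group
3	ether	[OD2]([#6;!$(C=O)])[#6;!$(C=O)]	COC	functional_group
4	aldehyde	[CX3H1](=O)[#6]	CC=O	functional_group
5	ketone	[#6][CX3](=O)[#6]	CC(C)=O	functional_group
6	carboxylic-acid	[CX3](=O)[OX2H1]	OC=O	functional_group
7	carboxylate	[CX3](=O)[O-]		functional_group
8	ester	[#6][CX3](=O)[OX2][#6]	COC(C)=O	functional_group
9	anhydride	[CX3](=O)[OX2][CX3](=O)	O=COC=O	functional_group
10	peroxide	[OX2][OX2]	OO	functional_group
11	epoxide	C1OC1	C1CO1	functional_group
12	oxetane	C1COC1	C1COC1	functional_group
13	tetrahydrofuran	C1CCOC1	C1CCOC1	functional_group
14	tetrahydropyran	C1CCOCC1	C1CCOCC1	functional_group
15	furan	c1ccoc1	c1ccoc1	functional_group
16	carbonate	[OX2][CX3](=O)[OX2]	COC(=O)OC	functional_group
17	dioxolane	C1OCCO1	C1OCCO1	functional_group
18	dioxane	C1COCCO1	C1COCCO1	functional_group
19	methylenedioxyphenyl	C1Oc2ccccc2O1	C1Oc2ccccc2O1	functional_group
20	primary-amine	[NX3;H2;!$(NC=O);!$(NS=O)]	N	functional_group
21	secondary-amine	[NX3;H1;!$(NC=O);!$(NS=O)]([#6])[#6]	CNC	functional_group
22	tertiary-amine	[NX3;H0;!$(NC=O);!$(N=O);!$(NS=O)]([#6])([#6])[#6]	CN(C)C	functional_group
23	quaternary-ammonium	[NX4+]		functional_group
24	amide	[NX3][CX3](=[OX1])	NC=O	functional_group
25	primary-amide	[NX3H2][CX3](=[OX1])	NC=O	functional_group
26	imine	[CX3]=[NX2]	C=N	functional_group
27	nitrile	[NX1]#[CX2]	C#N	functional_group
28	nitro	[#7X3](=[OX1])~[OX1]	[N+](=O)[O-]	functional_group
29	azide	[NX2]=[NX2+]=[NX1-]		functional_group
30	azo	[#6][NX2]=[NX2][#6]	CN=NC	functional_group
31	hydrazine	[NX3][NX3]	NN	functional_group
32	hydrazone	[NX3][NX2]=[CX3]	NN=C	functional_group
33	oxime	[NX2](=[CX3])[OX2H]	ON=C	functional_group
34	hydroxylamine	[NX3][OX2H]	NO	functional_group
35	nitroso	[NX2]=[OX1]	N=O	functional_group
36	guanidine	[NX3][CX3](=[NX2])[NX3]	NC(N)=N	functional_group
37	amidine	[NX3][CX3]=[NX2]	NC=N	functional_group
38	urea	[NX3][CX3](=[OX1])[NX3]	NC(N)=O	functional_group
39	carbamate	[NX3][CX3](=[OX1])[OX2][#6]	COC(N)=O	functional_group
40	isocyanate	[NX2]=[CX2]=[OX1]	N=C=O	functional_group
41	isothiocyanate	[NX2]=[CX2]=[SX1]	N=C=S	functional_group
42	aniline	[NX3][c]		functional_group
43	n-oxide	[#7X4+][OX1-]		functional_group
44	enamine	[NX3][CX3]=[CX3]	NC=C	functional_group
45	imide	[CX3](=[OX1])[NX3][CX3](=[OX1])	O=CNC=O	functional_group
46	pyridine	c1ccncc1	c1ccncc1	functional_group
47	pyrrole	c1cc[nH]c1	c1cc[nH]c1	functional_group
48	imidazole	c1cnc[nH]1	c1cnc[nH]1	functional_group
49	pyrazole	c1cc[nH]n1	c1cc[nH]n1	functional_group
50	oxazole	c1ocnc1	c1ocnc1	functional_group
51	isoxazole	c1oncc1	c1oncc1	functional_group
52	thiazole	c1scnc1	c1scnc1	functional_group
53	pyrimidine	c1cncnc1	c1cncnc1	functional_group
54	pyrazine	c1cnccn1	c1cnccn1	functional_group
55	pyridazine	c1ccnnc1	c1ccnnc1	functional_group
56	triazole-1H	c1cn[nH]n1	c1cn[nH]n1	functional_group
57	tetrazole	c1nn[nH]n1	c1nn[nH]n1	functional_group
58	indole	c1ccc2c(c1)cc[nH]2	c1ccc2c(c1)cc[nH]2	functional_group
59	benzimidazole	c1ccc2c(c1)nc[nH]2	c1ccc2c(c1)nc[nH]2	functional_group
60	benzofuran	c1ccc2c(c1)cco2	c1ccc2c(c1)cco2	functional_group
61	benzothiophene	c1ccc2c(c1)ccs2	c1ccc2c(c1)ccs2	functional_group
62	quinoline	c1ccc2ncccc2c1	c1ccc2ncccc2c1	functional_group
63	piperidine	C1CCNCC1	C1CCNCC1	functional_group
64	piperazine	C1CNCCN1	C1CNCCN1	functional_group
65	morpholine	C1COCCN1	C1COCCN1	functional_group
66	thiomorpholine	C1CSCCN1	C1CSCCN1	functional_group
67	pyrrolidine	C1CCNC1	C1CCNC1	functional_group
68	azetidine	C1CNC1	C1CNC1	functional_group
69	aziridine	C1CN1	C1CN1	functional_group
70	tetrahydrothiophene	C1CCSC1	C1CCSC1	functional_group
71	thiol	[SX2H]	S	functional_group
72	thioether	[#6][SX2][#6]	CSC	functional_group
73	disulfide	[SX2][SX2]	SS	functional_group
74	sulfoxide	[#16X3](=[OX1])([#6])[#6]	CS(C)=O	functional_group
75	sulfone	[#16X4](=[OX1])(=[OX1])([#6])[#6]	CS(C)(=O)=O	functional_group
76	sulfonamide	[#16X4](=[OX1])(=[OX1])[NX3]	NS(=O)=O	functional_group
77	sulfonic-acid	[#16X4](=[OX1])(=[OX1])[OX2H]	OS(=O)=O	functional_group
78	sulfonate-ester	[#16X4](=[OX1])(=[OX1])[OX2][#6]	COS(=O)=O	functional_group
79	sulfate-ester	[OX2][SX4](=[OX1])(=[OX1])[OX2]	COS(=O)(=O)OC	functional_group
80	thioamide	[NX3][CX3]=[SX1]	NC=S	functional_group
81	thiourea	[NX3][CX3](=[SX1])[NX3]	NC(N)=S	functional_group
82	thiocarbonyl	[CX3]=[SX1]	C=S	functional_group
83	thiocyanate	[SX2][CX2]#[NX1]	SC#N	functional_group
84	thiophene	c1ccsc1	c1ccsc1	functional_group
85	phosphate	[PX4](=[OX1])([OX2])([OX2])[OX2]	OP(=O)(O)O	functional_group
86	phosphonate	[PX4](=[OX1])([OX2])([OX2])[#6]	CP(=O)(O)O	functional_group
87	phosphine	[PX3]	P	functional_group
88	phosphine-oxide	[PX4]=[OX1]	CP(C)(C)=O	functional_group
89	boronic-acid	[BX3]([OX2H])[OX2H]	OB(O)C	functional_group
90	boronate-ester	[BX3]([OX2][#6])[OX2][#6]	COB(C)OC	functional_group
91	borane	[BX3]		functional_group
92	fluoro	[F][#6]	FC	functional_group
93	chloro	[Cl][#6]	ClC	functional_group
94	bromo	[Br][#6]	BrC	functional_group
95	iodo	[I][#6]	IC	functional_group
96	trifluoromethyl	[CX4]([F])([F])[F]	FC(F)F	functional_group
97	acyl-chloride	[CX3](=[OX1])[Cl]	CC(=O)Cl	functional_group
98	acetal	[CX4]([OX2][#6])[OX2][#6]	COC(C)OC	functional_group
99	hemiacetal	[CX4]([OX2H])[OX2][#6]	COC(C)O	functional_group
100	enol	[OX2H][CX3]=[CX3]	OC=C	functional_group
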