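mqtl_id	chromosome	marker_left	marker_right	position_cM	ci_cM	phys_lo_Mb	phys_hi_Mb	n_initial_qtls	n_populations	traits	n_genes
MQTL-1/Chr1	1	T7A14	EAT	7.91	0.71	2.66	2.77	24	9	shAl,B,shCa,Fe,shFe,K,shK,Mg,shMg,Mn,P,shP,S,Zn,rsZn	29
MQTL-2/Chr1	1	EC.480C	F3F19	17.86	0.29	4.31	4.60	11	7	B,Ca,Cd,Cu,Mn,Na,P,shP,Se,Zn	91
MQTL-3/Chr1	1	ARR7	g3829	24.63	1.3	6.58	7.09	16	8	B,Ca,Cd,Fe,K,Mg,Mn,rsMn,Na,S	170
MQTL-4/Chr1	1	g17286	MSAT108193	33.02	1.91	7.30	8.19	2	2	Mg,Na	258
MQTL-5/Chr1	1	AD.121C	mi342	43.33	1.85	10.16	11.41	5	5	K,Fe,Mn,P	335
MQTL-6/Chr1	1	SNP158	GB.112L	51.24	1.08	12.18	12.73	19	6	Ca,Co,Fe,K,Mg,P,Rb,Se,Zn	128
MQTL-7/Chr1	1	CH.192L-Col	HH.375L	70.62	1.94	22.00	23.49	32	9	As,B,Ca,Cu,shCu,Fe,K,Mg,Ni,P,rsP,Rb,S,Se,Zn,roZn	459
MQTL-8/Chr1	1	nga692	FD.90L-Col	94.16	0.11	28.01	28.84	10	7	Mn,Li,P,S,Zn	285
MQTL-1/Chr2	2	EC.495C-Col	FD.81L	15.06	1.46	4.96	5.30	10	5	Li,Ca,Cd,Co,Cu,K,Mg,P,Se	20
MQTL-2/Chr2	2	MSAT2.36	GB.150L-Col	33.36	3.57	8.69	9.98	14	9	B,Ca,shCa,K,rsK,rsMg,shMg,P,Zn	432
MQTL-3/Chr2	2	AD.191L-Col	SNP135	45.9	2.31	11.22	12.11	42	10	Ca,Cu,Fe,rsFe,K,Mg,rsMg,Mn,rsMn,Mo,Na,P,shS,Zn	237
MQTL-4/Chr2	2	SNP169	F17A22	58.42	2.61	17.64	19.56	11	7	Ca,Cu,K,Mg,Mo,Rb,Zn	693
MQTL-5/Chr2	2	g17288	g17477	64.45	0.45	16.29	16.78	3	3	Cu,K,Ni	160
MQTL-1/Chr3	3	SNP105	DF.252L	0.44	0.63	0.05	0.18	28	7	Ca,Fe,K,Li,Mg,rsMg,Mn,P,rsP,shP,S,Zn,rsZn	61
MQTL-2/Chr3	3	FAI228	CH.318E	5.16	1.32	0.79	1.08	15	7	Ca,K,roFe,rsMg,Mn,Mo,Na,P,rsP,Se,Zn,rsZn	99
MQTL-3/Chr3	3	NT204	CC.266L	14.78	1.21	4.95	5.57	17	8	Ca,shCa,Co,Cu,shCu,Fe,K,Mn,P,Se,Zn,shZn	220
MQTL-4/Chr3	3	SNP35	MSAT3.19	23.55	1.51	8.17	8.81	9	5	Co,Cu,Mg,rsMg,Mn,rsP,Zn,rsZn	175
MQTL-5/Chr3	3	GD.136C-Col	BF.121E-Col	43.91	0.87	14.53	14.72	14	7	Cu,Fe,Mg,Mn,rsMn,P,S,Zn,rsZn	9
MQTL-6/Chr3	3	nga6	SNP264	70.42	0.38	23.04	23.39	9	6	Cu,K,P,shP,S,shS,Zn	131
MQTL-1/Chr4	4	MSAT4.8	app1	2.41	1.04	0.41	0.90	17	4	Ca,Fe,rsFe,K,rsK,Mg,Mn,Na,P,rsP,Rb,S,rsZn	154
MQTL-2/Chr4	4	SNP292	nga1111	30.53	2.29	5.87	6.09	13	5	B,Ca,rsCa,Fe,rsFe,K,rsK,Na,Se,Zn,rsZn	774
MQTL-3/Chr4	4	g2883	CH.104E	40.23	1.35	6.25	6.62	8	3	Ca,K,Mg,Mn,rsMn,P,shS,Zn	97
MQTL-4/Chr4	4	DF.125L	MSAT4.18	51.1	1.08	11.52	11.97	25	10	Ca,rsCa,Cd,Cu,K,rsK,Mg,rsMg,Mn,rsMn,Mo,Na,P,S,Se,Zn,rsZn	150
MQTL-5/Chr4	4	nga1107	mi369	75.49	0.1	18.10	18.54	12	6	B,Ca,Cu,shCu,Mg,Mn,shMn,Na,shP,Zn	161
MQTL-1/Chr5	5	CH.690C	PDC3	5.4	0.96	0.77	1.32	11	4	shAl,B,Ca,shCa,Fe,K,Mn,shMn	170
MQTL-2/Chr5	5	DF.231C	SNP77	26.02	1.29	3.46	5.64	20	7	B,Ca,rsCa,Co,Fe,K,shK,Mg,Mn,rsMn,Na,P,rsP,shP,S,rsZn	692
MQTL-3/Chr5	5	m291	BH.127L	37.21	1.29	6.68	7.49	28	9	shAl,rsCa,shCa,Co,Cu,Fe,shFe,K,Mg,shMg,Mn,Na,P,S,Zn,shZn	252
MQTL-4/Chr5	5	aw22	SNP193	45.47	1.96	8.50	8.79	13	6	Ca,K,rsFe,shFe,Li,Mg,Mn,P,Zn	69
MQTL-5/Chr5	5	mi125	EC.395C	55.24	2.37	12.91	13.28	5	4	Fe,rsMn,Rb,S,shS	21
MQTL-6/Chr5	5	MSAT5.8	AD.254C	70.77	0.91	15.46	17.35	7	4	Cu,Fe,K,Mg,Mn	585
MQTL-7/Chr5	5	HH.445L-Col	MSAT518662	79.5	0.98	18.66	20.66	7	6	Fe,K,shMg,P,S,Zn	608
MQTL-8/Chr5	5	h2a1	HH.143C	89.58	1.51	22.39	23.30	10	6	B,Cu,K,Mn,Na,P,S,Zn	283
MQTL-9/Chr5	5	MSAT5.19	FD.188C	104.22	0.1	24.53	25.92	16	7	Ca,Co,K,Li,Mg,rsMn,Rb,rsFe,rsP,S,Zn	468
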