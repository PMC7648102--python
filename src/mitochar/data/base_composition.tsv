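# Published base-composition table for the two limpet mitogenomes
# (Lg = Lottia goshimai, Nf = Nipponacmea fuscoviridis).  Percentages as
# printed (2 d.p. except the Lg PCGs C% cell, which prints 19.178); skews as
# printed (3 d.p.).  Used as a regression fixture for the skew formulas.
Region	Species	Size	A	T	G	C	AT	ATskew	GCskew
Mitogenome	Lg	18192	28.18	32.00	24.11	15.71	60.17	-0.063	0.211
Mitogenome	Nf	18720	23.83	30.32	25.39	20.46	54.15	-0.120	0.108
cox1	Lg	1560	24.49	36.15	24.04	15.32	60.64	-0.192	0.222
cox1	Nf	1551	22.63	34.62	24.37	18.38	57.25	-0.209	0.140
cox2	Lg	666	31.68	27.48	16.67	24.17	59.16	0.071	-0.184
cox2	Nf	688	25.30	27.43	28.02	19.25	52.73	-0.090	0.253
cox3	Lg	805	25.59	32.55	18.88	22.98	58.14	-0.120	-0.098
cox3	Nf	787	20.08	35.58	26.94	17.41	55.65	-0.272	0.265
nad1	Lg	930	26.13	34.52	16.99	22.37	60.65	-0.138	-0.137
nad1	Nf	936	20.73	35.04	28.10	16.13	55.77	-0.257	0.271
nad2	Lg	963	28.45	30.43	16.20	24.92	58.88	-0.034	-0.212
nad2	Nf	1038	21.39	31.31	18.69	28.61	52.70	-0.188	-0.210
nad3	Lg	346	20.81	40.75	26.88	11.56	61.56	-0.324	0.399
nad3	Nf	354	18.64	33.62	31.07	16.67	52.26	-0.287	0.302
nad4	Lg	1326	20.44	39.44	26.24	13.88	59.88	-0.317	0.308
nad4	Nf	1302	21.89	30.18	20.35	27.57	52.07	-0.159	-0.151
nad4l	Lg	284	20.77	37.32	29.58	12.32	58.10	-0.285	0.412
nad4l	Nf	297	22.90	33.33	22.90	20.88	56.23	-0.185	0.046
nad5	Lg	1674	29.57	31.66	14.22	24.55	61.23	-0.034	-0.266
nad5	Nf	1614	24.10	28.62	17.97	29.31	52.73	-0.086	-0.240
nad6	Lg	519	18.30	43.93	24.28	13.49	62.24	-0.412	0.286
nad6	Nf	489	23.31	32.31	30.06	14.31	55.62	-0.162	0.355
cytb	Lg	1159	21.74	40.90	20.97	16.39	62.64	-0.306	0.123
cytb	Nf	1135	20.88	34.45	25.81	18.85	55.33	-0.245	0.156
atp6	Lg	762	28.35	32.28	15.49	23.88	60.63	-0.065	-0.213
atp6	Nf	801	20.72	34.58	27.59	17.10	55.31	-0.251	0.235
atp8	Lg	115	20.00	35.65	20.87	23.48	55.65	-0.281	-0.059
atp8	Nf	162	22.22	33.33	23.46	20.99	55.56	-0.200	0.056
tRNAs	Lg	1558	28.75	27.66	24.65	18.93	56.42	0.019	0.131
tRNAs	Nf	1597	24.92	27.49	26.61	20.98	52.41	-0.049	0.118
rRNAs	Lg	2494	28.47	28.03	25.54	17.96	56.50	0.008	0.174
rRNAs	Nf	2374	27.38	25.06	28.52	19.04	52.44	0.044	0.199
PCGs	Lg	11238	24.33	35.62	20.87	19.178	59.95	-0.188	0.042
PCGs	Nf	11154	21.91	32.65	25.03	20.42	54.55	-0.197	0.101
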