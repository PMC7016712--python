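isolate	line	position	change	coverage	frequency	p_value	support	feature	effect	de_novo
AF16	Progenitor	3567	(A)10 → (A)11	402	0.015	3.3e-10	6	atp-6	None	False
AF16	MA3	3567	(A)10 → (A)11	374	0.013	5.5e-08	5	atp-6	None	False
AF16	MA3	6515	(T)7 → (T)6	289	0.266	2.7e-69	77	ctc-3	Frame Shift	True
AF16	MA3	8305	(T)9 → (T)10	362	0.014	4.8e-09	5	-	-	False
AF16	MA4	8305	(T)9 → (T)10	341	0.018	3.2e-11	6	-	-	False
AF16	MA4	12601	(T)8 → (T)9	333	0.027	7.5e-18	9	nduo-5	Frame Shift	True
AF16	MA10	8305	(T)9 → (T)8	196	0.276	5.6e-50	54	Psi-nad5-2	-	False
AF16	MA10	12276	(T)5 → (T)4	214	0.084	1.4e-08	18	-	-	False
AF16	MA12	3567	(A)10 → (A)11	340	0.032	2.3e-22	11	atp-6	None	False
ED3101	Progenitor	3618	(A)12 → (A)13	302	0.060	1.6e-40	18	atp-6	None	False
ED3101	Progenitor	5041	(T)9 → (T)10	280	0.061	1.7e-38	17	-	-	False
ED3101	MA25	3618	(A)12 → (A)13	216	0.032	9.6e-15	7	atp-6	None	False
ED3101	MA25	8357	(T)9 → (T)10	266	0.026	4.2e-14	7	-	-	False
ED3101	MA25	12230	(T)9 → (T)10	228	0.057	2.0e-29	13	nduo-3	Frame Shift	False
ED3101	MA27	3582	(T)6 → (T)7	234	0.030	1.7e-14	7	atp-6	Frame Shift	True
ED3101	MA27	3618	(A)12 → (A)13	214	0.051	1.3e-24	11	atp-6	None	False
ED3101	MA27	8357	(T)9 → (T)10	284	0.018	1.4e-09	5	-	-	False
ED3101	MA27	12124	(T)7 → (T)8	238	0.050	1.3e-26	12	nduo-3	Frame Shift	True
ED3101	MA33	3618	(A)12 → (A)13	233	0.056	2.6e-29	13	atp-6	None	False
ED3101	MA33	6930	(A)6 → (A)5	302	0.066	1.2e-07	20	ctc-3	Frame Shift	True
ED3101	MA33	7355	(T)8 → (T)9	309	0.019	1.8e-11	6	nduo-4	Frame Shift	True
ED3101	MA35	3618	(A)12 → (A)11	294	0.112	4.1e-21	33	atp-6	None	False
ED3101	MA35	3618	(A)12 → (A)13	292	0.055	1.3e-35	16	atp-6	None	False
ED3101	MA35	8357	(T)9 → (T)10	287	0.014	6.8e-08	4	-	-	False
ED3101	MA47	576	(T)8 → (T)9	255	0.278	2.7e-206	71	nduo-6	Frame Shift	False
ED3101	MA47	3618	(A)12 → (A)13	258	0.089	1.6e-55	23	atp-6	None	False
AF16	MA3	402	G → T	143	0.699	0	100	tRNA-Val	-	True
AF16	MA12	3707	G → T	337	0.015	1.1e-08	5	tRNA-Ser	-	True
AF16	MA12	8092	G → T	217	0.041	1.2e-18	9	nduo-4	S → I Sub	False
AF16	MA13	630	C → T	163	0.245	2.0e-110	40	nduo-6	None	False
AF16	MA13	2270	T → A	222	0.072	5.8e-36	16	nduo-1	Truncation	True
ED3101	Progenitor	3414	C → T	287	0.404	0	116	atp-6	S → L Sub	False
ED3101	MA27	11162	C → T	291	0.038	3.2e-24	11	l-rRNA	-	True
ED3101	MA33	670	G → T	251	0.068	4.9e-41	17	nduo-6	S → I Sub	True
ED3101	MA35	3414	C → T	281	0.299	3.5e-255	84	atp-6	S → L Sub	False
ED3101	MA47	3414	C → T	260	1.000	0	260	atp-6	S → L Sub	False
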