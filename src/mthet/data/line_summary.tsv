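isolate	line	role	generations	raw_read_pairs	input_reads	raw_mt_cov	raw_mt_sd	norm_mt_cov	norm_mt_sd	ama1_cov	ama1_sd	efl2_cov	efl2_sd	ego1_cov	ego1_sd
AF16	Progenitor	progenitor	0	2603066	2366924	361	49.7	65.43	9.008	4.4	3.03	5.6	2.86	6.50	3.01
AF16	MA4	MA	49	2608998	2376290	354.6	48.55	49.63	6.794	6.0	2.9	7.8	2.62	7.58	2.85
AF16	MA3	MA	46	2276257	2049378	346.1	41.63	60.23	7.244	5.5	3.34	6.4	1.36	5.33	2.46
AF16	MA13	MA	50	2265875	2067734	200.2	55.59	30.31	8.42	5.9	2.14	7.2	1.11	6.78	3.02
AF16	MA12	MA	42	2611375	2404412	274.1	67.58	41.19	10.16	5.2	2.2	8.2	2.73	6.58	2.7
AF16	MA10	MA	48	2742185	2505013	275.1	69.28	39.82	10.03	7.8	2.76	7.1	2.57	5.87	2.35
ED3101	Progenitor	progenitor	0	3503305	3217360	299.8	27.94	51.46	4.797	5.8	3.36	6.2	2.32	5.45	2.37
ED3101	MA25	MA	50	3915576	2969457	286	47.68	48.39	8.068	5.5	3.39	7.1	2.66	5.13	2.72
ED3101	MA27	MA	47	4010572	3430620	302.1	45.25	46.06	6.901	6.8	3.25	6.3	2.44	6.50	3.63
ED3101	MA33	MA	50	4104196	3245243	264.4	33.73	43.17	5.507	5.8	2.98	6.7	2.39	5.80	3.17
ED3101	MA35	MA	50	3573465	3250232	279.2	28.26	48.17	4.876	6.3	3.31	5.9	1.59	5.18	2.03
ED3101	MA47	MA	47	3699368	3393866	271	27.61	48.3	4.92	6.0	3.29	5.4	3.05	5.43	2.74
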