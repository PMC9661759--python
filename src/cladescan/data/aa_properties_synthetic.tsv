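property	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
Alpha-helical tendencies	1.42	0.7	1.01	1.51	1.13	0.57	1	1.08	1.16	1.21	1.45	0.67	0.57	1.11	0.98	0.77	0.83	1.06	1.08	0.69
Average number of surrounding residues	6.05	7.41	4.95	5.1	7.36	6.16	5.8	7.51	4.88	7.37	7.25	5.04	5.65	5.45	5.7	5.53	5.81	7.62	7.21	6.73
Beta-structure tendencies	0.83	1.19	0.54	0.37	1.38	0.75	0.87	1.6	0.74	1.3	1.05	0.89	0.55	1.1	0.93	0.75	1.19	1.7	1.37	1.47
Bulkiness	11.5	13.46	11.68	13.57	19.8	3.4	13.69	21.4	15.71	21.4	16.25	12.82	17.43	14.45	14.28	9.47	15.77	21.57	21.67	18.03
Buriedness	0.38	0.5	0.15	0.18	0.48	0.36	0.17	0.6	0.03	0.45	0.4	0.12	0.18	0.07	0.01	0.22	0.23	0.54	0.27	0.15
Chromatographic index	9.9	2.8	2.8	3.2	18.8	5.6	8.2	17.1	3.5	17.6	14.9	5.4	14.8	9	4.6	6.9	9.5	14.3	17.1	15
Coil tendencies	0.71	1.19	1.21	0.84	0.71	1.52	1.07	0.66	0.99	0.69	0.59	1.37	1.61	0.87	1.06	1.34	1.08	0.63	0.76	1.07
Composition	0	2.75	1.38	0.92	0	0.74	0.58	0	0.33	0	0	1.33	0.39	0.89	0.65	1.42	0.71	0	0.13	0.2
Compressibility	-25.5	-32.8	-33.1	-36.2	-34.5	-27	-31.2	-31.8	-29.7	-31.8	-31.4	-30.9	-23.3	-32.6	-26.7	-29.3	-27.9	-30.7	-30.5	-34.3
Equilibrium constant (ionization of COOH)	2.34	1.96	1.88	2.19	1.83	2.34	1.82	2.36	2.18	2.36	2.28	2.02	1.99	2.17	2.17	2.21	2.09	2.32	2.83	2.2
Helical contact area	94	130	99	116	194	70	155	160	164	164	172	113	120	134	192	85	115	135	227	196
Hydropathy	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
Isoelectric point	6	5.05	2.77	3.22	5.48	5.97	7.59	6.02	9.74	5.98	5.74	5.41	6.3	5.65	10.76	5.68	5.66	5.96	5.89	5.66
Long-range non-bonded energy	-0.86	-2.14	-1.05	-0.87	-2.04	-0.82	-1.63	-1.68	-0.77	-1.55	-1.6	-1.08	-1.29	-1.03	-1.14	-1.05	-1.17	-1.43	-2.26	-1.86
Mean r.m.s. fluctuation displacement	0.25	0.17	0.29	0.28	0.1	0.32	0.2	0.22	0.27	0.21	0.18	0.28	0.3	0.28	0.29	0.35	0.27	0.23	0.13	0.19
Molecular volume	31	55	54	83	132	3	96	111	119	111	105	56	32.5	85	124	32	61	84	170	136
Molecular weight	89.09	121.15	133.1	147.13	165.19	75.07	155.16	131.17	146.19	131.17	149.21	132.12	115.13	146.15	174.2	105.09	119.12	117.15	204.23	181.19
Normalized consensus hydrophobicity	0.62	0.29	-0.9	-0.74	1.19	0.48	-0.4	1.38	-1.5	1.06	0.64	-0.78	0.12	-0.85	-2.53	-0.18	-0.05	1.08	0.81	0.26
Partial specific volume	0.748	0.631	0.579	0.643	0.774	0.632	0.67	0.884	0.789	0.884	0.708	0.619	0.774	0.674	0.666	0.613	0.689	0.847	0.734	0.712
Polar requirement	7	4.8	13	12.5	5	7.9	8.4	4.9	10.1	4.9	5.3	10	6.6	8.6	9.1	7.5	6.6	5.6	5.2	5.4
Polarity	8.1	5.5	13	12.3	5.2	9	10.4	5.2	11.3	4.9	5.7	11.6	8	10.5	10.5	9.2	8.6	5.9	5.4	6.2
Power to be at the C-terminal	0.96	1.19	0.8	0.62	1.12	1	1.07	1.1	1.19	1.11	1.07	1.13	1.33	0.87	1.02	1.05	1	0.96	1.01	1.15
Power to be at the middle of alpha-helix	1.29	0.79	0.94	1.4	1.13	0.56	1.09	1.05	1.2	1.31	1.24	0.83	0.52	1.22	1.11	0.78	0.87	0.98	1.18	0.83
Power to be at the N-terminal	1.04	0.95	1.42	1.43	0.92	0.71	0.89	0.92	1.01	0.98	0.95	0.97	1.52	1.15	0.99	1	1.04	0.94	0.94	0.9
Refractive index	4.34	35.77	13.28	17.56	29.4	0	21.81	19.06	21.29	18.78	21.64	13.28	10.93	17.26	26.66	6.35	11.01	13.92	42.53	31.53
Short and medium range non-bonded energy	-0.49	-0.84	-0.51	-0.5	-0.94	-0.48	-0.69	-0.76	-0.49	-0.72	-0.71	-0.53	-0.73	-0.52	-0.54	-0.55	-0.58	-0.67	-0.89	-0.8
Solvent accessible reduction ratio	0.74	0.91	0.62	0.62	0.88	0.72	0.78	0.88	0.52	0.85	0.85	0.63	0.64	0.62	0.64	0.66	0.7	0.86	0.85	0.76
Surrounding hydrophobicity	12.97	14.63	10.85	11.89	14	12.43	12.16	15.67	11.36	14.9	14.39	11.42	11.37	11.76	11.72	11.23	11.69	15.71	13.93	13.42
Thermodynamic transfer hydrophobicity	0.5	1	-0.5	-0.5	2.5	0	0.5	1.8	-1	1.8	1.3	-0.5	1.4	-0.5	-1	-0.3	0.4	1.5	3.4	2.3
Total non-bonded energy	-1.35	-2.98	-1.56	-1.37	-2.98	-1.3	-2.32	-2.44	-1.26	-2.27	-2.31	-1.61	-2.02	-1.55	-1.68	-1.6	-1.75	-2.1	-3.15	-2.66
Turn tendencies	0.66	1.19	1.46	0.74	0.6	1.56	0.95	0.47	1.01	0.59	0.6	1.56	1.52	0.98	0.95	1.43	0.96	0.5	0.96	1.14
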