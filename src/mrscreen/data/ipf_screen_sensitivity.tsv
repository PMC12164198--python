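label	category	ivw_sign	egger_lnor	egger_ci_low	egger_ci_high	egger_p	wm_lnor	wm_ci_low	wm_ci_high	wm_p	presso_lnor	presso_ci_low	presso_ci_high	presso_p
2-Aminobutyrate	Amino acid	1	2.73	-1.70	7.16	0.2340	1.39	-0.76	3.53	0.2105	1.82	0.62	3.02	0.0048
Alpha-hydroxyisovalerate	Amino acid	1	-0.69	-3.70	2.32	0.6595	0.42	-1.13	1.97	0.5968	1.12	0.08	2.16	0.0538
Glucose	Carbohydrate	1	1.98	-1.74	5.70	0.3034	1.35	-1.30	4.00	0.3351	1.92	0.31	3.53	0.0253
Alpha-ketoglutarate	Energy	1	1.80	-0.25	3.86	0.1065	1.46	-0.07	3.00	0.0700	1.06	0.14	1.98	0.0378
Nonadecanoate (19:0)	Lipid	1	2.38	-0.28	5.04	0.1019	1.47	-0.49	3.43	0.1435	1.65	0.48	2.84	0.0147
Taurocholate	Lipid	1	0.30	-0.41	1.02	0.4192	0.56	-0.12	1.24	0.0904	0.42	0.01	0.83	0.0629
Octanoylcarnitine	Lipid	-1	-0.70	-2.39	0.99	0.4315	-0.76	-2.02	0.50	0.2518	-1.34	-2.27	-0.41	0.0121
Epiandrosterone sulfate	Lipid	-1	-0.68	-1.36	-0.01	0.0738	-0.70	-1.35	-0.05	0.0323	-0.75	-1.21	-0.29	0.0073
1-Linoleoylglycerophosphocholine	Lipid	-1	-3.47	-8.54	1.60	0.2030	-0.85	-3.45	1.75	0.5071	-1.93	-3.40	-0.45	0.0227
Dihomo-linolenate (20:3n3 or n6)	Lipid	-1	-0.68	-4.90	3.55	0.7571	-1.44	-3.49	0.61	0.1679	-1.79	-3.19	-0.39	0.0201
n-Butyl oleate	Lipid	1	4.10	-0.31	8.5	0.1058	3.36	0.97	5.75	0.0049	2.12	0.49	3.76	0.0315
Palmitoyl sphingomyelin	Lipid	-1	3.62	-2.59	9.82	0.2592	-1.19	-3.42	1.04	0.3100	-1.63	-3.05	-0.21	0.0291
Pyroglutamylglycine	Peptide	1	0.98	-2.11	4.07	0.5980	1.05	-0.23	2.23	0.1043	1.00	0.28	1.73	0.0727
1,7-Dimethylurate	Xenobiotics	1	0.90	-0.56	2.36	0.2557	1.03	-0.11	2.17	0.1039	0.93	0.37	1.49	0.0075
X-10810	Unknown	-1	-0.81	-2.26	0.64	0.2898	-1.13	-2.53	0.26	0.1282	-1.12	-1.86	-0.36	0.0110
X-11491	Unknown	1	0.56	-0.71	1.84	0.4049	0.40	-0.51	1.32	0.3576	0.68	0.05	1.31	0.0569
X-11850	Unknown	1	0.70	-0.08	1.48	0.1397	0.50	-0.09	1.09	0.1016	0.54	0.18	0.89	0.0246
X-11852	Unknown	-1	-0.91	-1.57	-0.26	0.0296	-0.38	-0.98	0.22	0.2118	-0.45	-0.86	-0.04	0.0632
X-12644	Unknown	-1	-2.17	-4.54	0.21	0.0874	-1.84	-3.37	-0.32	0.0173	-1.11	-2.21	-0.02	0.0584
X-12786	Unknown	-1	-0.98	-2.83	0.87	0.3254	-1.02	-2.45	0.41	0.1660	-1.22	-2.00	-0.43	0.0129
X-13548	Unknown	1	3.13	-1.31	7.56	0.1746	1.15	-1.12	3.42	0.3099	1.58	0.14	3.03	0.0373
X-13671	Unknown	-1	-0.40	-8.44	7.64	0.9242	-2.04	-5.02	0.93	0.1420	-3.14	-4.94	-1.34	0.0042
X-14745	Unknown	-1	-4.19	-13.86	5.48	0.4159	-1.25	-3.43	0.93	0.2522	-1.60	-3.17	-0.02	0.0720
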