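label	category	r2_exposure	r2_outcome	steiger_p
2-Aminobutyrate	Amino acid	0.1466	1.83e-04	1.81e-235
Alpha-hydroxyisovalerate	Amino acid	0.0910	9.07e-05	1.05e-119
Glucose	Carbohydrate	0.1505	1.71e-04	5.02e-224
Alpha-ketoglutarate	Energy	0.0883	8.68e-05	3.03e-101
Nonadecanoate (19:0)	Lipid	0.0829	7.96e-05	1.41e-105
Taurocholate	Lipid	0.2139	9.19e-05	1.55e-147
Octanoylcarnitine	Lipid	0.1089	1.32e-04	4.35e-171
Epiandrosterone sulfate	Lipid	0.1233	1.28e-04	1.18e-181
1-Linoleoylglycerophosphocholine	Lipid	0.0725	6.80e-05	3.50e-96
Dihomo-linolenate (20:3n3 or n6)	Lipid	0.0979	1.48e-04	4.00e-142
n-Butyl oleate	Lipid	0.0505	7.36e-05	4.93e-45
Palmitoyl sphingomyelin	Lipid	0.1503	2.16e-04	8.10e-240
Pyroglutamylglycine	Peptide	0.0793	2.80e-05	3.25e-22
1,7-Dimethylurate	Xenobiotics	0.0951	5.18e-05	3.30e-95
X-10810	Unknown	0.0653	6.68e-05	5.11e-88
X-11491	Unknown	0.0956	8.62e-05	5.02e-113
X-11850	Unknown	0.0460	4.52e-05	3.24e-41
X-11852	Unknown	0.0995	5.90e-05	6.42e-53
X-12644	Unknown	0.0981	1.53e-04	1.14e-139
X-12786	Unknown	0.0618	5.69e-05	5.35e-70
X-13548	Unknown	0.1940	2.06e-04	3.93e-244
X-13671	Unknown	0.0512	1.04e-04	5.93e-72
X-14745	Unknown	0.0491	8.05e-05	2.44e-54
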