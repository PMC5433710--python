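property	aaindex_id	description	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
alpha_helical_tendencies	CHOP780201	Normalized frequency of alpha-helix (Chou-Fasman, 1978b)	1.42	0.98	0.67	1.01	0.7	1.11	1.51	0.57	1	1.08	1.21	1.16	1.45	1.13	0.57	0.77	0.83	1.08	0.69	1.06
average_surrounding_residues	PONP800108	Average number of surrounding residues (Ponnuswamy et al., 1980)	6.05	5.7	5.04	4.95	7.86	5.45	5.1	6.16	5.8	7.51	7.37	4.88	6.39	6.62	5.65	5.53	5.81	6.98	6.73	7.62
beta_structure_tendencies	CHOP780202	Normalized frequency of beta-sheet (Chou-Fasman, 1978b)	0.83	0.93	0.89	0.54	1.19	1.1	0.37	0.75	0.87	1.6	1.3	0.74	1.05	1.38	0.55	0.75	1.19	1.37	1.47	1.7
bulkiness	ZIMJ680102	Bulkiness (Zimmerman et al., 1968)	11.5	14.28	12.82	11.68	13.46	14.45	13.57	3.4	13.69	21.4	21.4	15.71	16.25	19.8	17.43	9.47	15.77	21.67	18.03	21.57
buriedness	WERD780101	Propensity to be buried inside (Wertz-Scheraga, 1978)	0.52	0.49	0.42	0.37	0.83	0.35	0.38	0.41	0.7	0.79	0.77	0.31	0.76	0.87	0.35	0.49	0.38	0.86	0.64	0.72
chromatographic_index	WEBA780101	RF value in high salt chromatography (Weber-Lacey, 1978)	0.89	0.88	0.89	0.87	0.85	0.82	0.84	0.92	0.83	0.76	0.73	0.97	0.74	0.52	0.82	0.96	0.92	0.2	0.49	0.85
coil_tendencies	NAGK730103	Normalized frequency of coil (Nagano, 1973)	0.72	1.33	1.38	1.04	1.01	0.81	0.75	1.35	0.76	0.8	0.63	0.84	0.62	0.58	1.43	1.34	1.03	0.87	1.35	0.83
composition	GRAR740101	Composition (Grantham, 1974)	0	0.65	1.33	1.38	2.75	0.89	0.92	0.74	0.58	0	0	0.33	0	0	0.39	1.42	0.71	0.13	0.2	0
mean_flexibility	BHAR880101	Average flexibility indices (Bhaskaran-Ponnuswamy, 1988)	0.357	0.529	0.463	0.511	0.346	0.493	0.497	0.544	0.323	0.462	0.365	0.466	0.295	0.314	0.509	0.507	0.444	0.305	0.42	0.386
equilibrium_constant_cooh	JOND750102	pK (-COOH) (Jones, 1975)	2.34	1.18	2.02	2.01	1.65	2.17	2.19	2.34	1.82	2.36	2.36	2.18	2.28	1.83	1.99	2.21	2.1	2.38	2.2	2.32
helical_contact_area	ROSG850101	Mean area buried on transfer (Rose et al., 1985)	86.6	162.2	103.3	97.8	132.3	119.2	113.9	62.9	155.8	158	164.1	115.5	172.9	194.1	92.9	85.6	106.5	224.6	177.7	141
hydropathy	KYTJ820101	Hydropathy index (Kyte-Doolittle, 1982)	1.8	-4.5	-3.5	-3.5	2.5	-3.5	-3.5	-0.4	-3.2	4.5	3.8	-3.9	1.9	2.8	-1.6	-0.8	-0.7	-0.9	-1.3	4.2
isoelectric_point	ZIMJ680104	Isoelectric point (Zimmerman et al., 1968)	6	10.76	5.41	2.77	5.05	5.65	3.22	5.97	7.59	6.02	5.98	9.74	5.74	5.48	6.3	5.68	5.66	5.89	5.66	5.96
long_range_nonbonded_energy	OOBM770103	Long range non-bonded energy per atom (Oobatake-Ooi, 1977)	-0.491	-0.554	-0.382	-0.356	-0.67	-0.405	-0.371	-0.534	-0.54	-0.762	-0.65	-0.3	-0.659	-0.729	-0.463	-0.455	-0.515	-0.839	-0.656	-0.728
mean_rms_fluctuation	VINM940101	Normalized flexibility parameters (B-values), average (Vihinen et al., 1994)	0.984	1.008	1.048	1.068	0.906	1.037	1.094	1.031	0.95	0.927	0.935	1.102	0.952	0.915	1.049	1.046	0.997	0.904	0.929	0.931
molecular_volume	GRAR740103	Volume (Grantham, 1974)	31	124	56	54	55	85	83	3	96	111	111	119	105	132	32.5	32	61	170	136	84
molecular_weight	FASG760101	Molecular weight (Fasman, 1976)	89.09	174.2	132.12	133.1	121.15	146.15	147.13	75.07	155.16	131.17	131.17	146.19	149.21	165.19	115.13	105.09	119.12	204.24	181.19	117.15
normalized_consensus_hydrophobicity	EISD840101	Consensus normalized hydrophobicity scale (Eisenberg, 1984)	0.25	-1.76	-0.64	-0.72	0.04	-0.69	-0.62	0.16	-0.4	0.73	0.53	-1.1	0.26	0.61	-0.07	-0.26	-0.18	0.37	0.02	0.54
partial_specific_volume	COHE430101	Partial specific volume (Cohn-Edsall, 1943)	0.75	0.7	0.61	0.6	0.61	0.67	0.66	0.64	0.67	0.9	0.9	0.82	0.75	0.77	0.76	0.68	0.7	0.74	0.71	0.86
polar_requirement	WOEC730101	Polar requirement (Woese, 1973)	7	9.1	10	13	5.5	8.6	12.5	7.9	8.4	4.9	4.9	10.1	5.3	5	6.6	7.5	6.6	5.3	5.7	5.6
polarity	GRAR740102	Polarity (Grantham, 1974)	8.1	10.5	11.6	13	5.5	10.5	12.3	9	10.4	5.2	4.9	11.3	5.7	5.2	8	9.2	8.6	5.4	6.2	5.9
power_helix_c_terminal	CHOP780205	Normalized frequency of C-terminal helix (Chou-Fasman, 1978b)	1.2	1.25	0.59	0.61	1.11	1.22	1.24	0.42	1.77	0.98	1.13	1.83	1.57	1.1	0	0.96	0.75	0.4	0.73	1.25
power_helix_middle	CRAJ730101	Normalized frequency of middle helix (Crawford et al., 1973)	1.33	0.79	0.72	0.97	0.93	1.42	1.66	0.58	1.49	0.99	1.29	1.03	1.4	1.15	0.49	0.83	0.94	1.33	0.49	0.96
power_helix_n_terminal	CHOP780204	Normalized frequency of N-terminal helix (Chou-Fasman, 1978b)	1.29	0.44	0.81	2.02	0.66	1.22	2.44	0.76	0.73	0.67	0.58	0.66	0.71	0.61	2.01	0.74	1.08	1.47	0.68	0.61
refractive_index	MCMT640101	Refractivity (McMeekin et al., 1964), Cited by Jones (1975)	4.34	26.66	13.28	12	35.77	17.56	17.26	0	21.81	19.06	18.78	21.29	21.64	29.4	10.93	6.35	11.01	42.53	31.53	13.92
short_medium_range_nonbonded_energy	OOBM770102	Short and medium range non-bonded energy per atom (Oobatake-Ooi, 1977)	-1.404	-0.921	-1.178	-1.162	-1.365	-1.116	-1.163	-1.364	-1.215	-1.189	-1.315	-1.074	-1.303	-1.135	-1.236	-1.297	-1.252	-1.03	-1.03	-1.254
solvent_accessible_reduction_ratio	PONP800107	Accessibility reduction ratio (Ponnuswamy et al., 1980)	3.7	2.53	2.12	2.6	3.03	2.7	3.3	3.13	3.57	7.69	5.88	1.79	5.21	6.6	2.12	2.43	2.6	6.25	3.03	7.14
surrounding_hydrophobicity	PONP800101	Surrounding hydrophobicity in folded form (Ponnuswamy et al., 1980)	12.28	11.49	11	10.97	14.93	11.28	11.19	12.01	12.84	14.77	14.1	10.8	14.33	13.43	11.19	11.26	11.65	12.95	13.29	15.07
thermodynamic_transfer_hydrophobicity	NOZY710101	Transfer energy, organic solvent/water (Nozaki-Tanford, 1971)	0.5	0	0	0	0	0	0	0	0.5	1.8	1.8	0	1.3	2.5	0	0	0.4	3.4	2.3	1.5
total_nonbonded_energy	OOBM770101	Average non-bonded energy per atom (Oobatake-Ooi, 1977)	-1.895	-1.475	-1.56	-1.518	-2.035	-1.521	-1.535	-1.898	-1.755	-1.951	-1.966	-1.374	-1.963	-1.864	-1.699	-1.753	-1.767	-1.869	-1.686	-1.981
turn_tendencies	CHOP780101	Normalized frequency of beta-turn (Chou-Fasman, 1978a)	0.66	0.95	1.56	1.46	1.19	0.98	0.74	1.56	0.95	0.47	0.59	1.01	0.6	0.6	1.52	1.43	0.96	0.96	1.14	0.5
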