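protein	seq_id	outcome	n_inst	f_stat	log2fc	trait_change	beta	se	p	concordant	outcome_type
AGER	4125_52	eGFRcrea	1	1352	0.092	Up	-0.029	0.004	4.41E-16	0	continuous
CPNE1	5346_24	LDL	3	3026	-0.262	Down	-0.029	0.002	4.40E-42	1	continuous
CPNE1	5346_24	triglycerides	3	3026	-0.262	Down	-0.017	0.002	1.53E-15	1	continuous
CPNE1	5346_24	type II diabetes	3	3026	-0.262		0.026	0.006	3.81E-06		binary
CSK	3363_31	diastolic blood pressure	1	53	-0.246	Up	-0.425	0.065	8.55E-11	0	continuous
CSK	3363_31	LDL	1	53	-0.246	Down	0.159	0.033	1.27E-06	0	continuous
CSK	3363_31	systolic blood pressure	1	53	-0.246	Up	-0.306	0.05	1.20E-09	0	continuous
FCGR2B	3310_62	LDL	3	18092	0.044	Down	-0.007	0.002	3.64E-05	1	continuous
GP1BA	4990_87	LDL	1	288	-0.046	Down	0.047	0.011	9.88E-06	0	continuous
ICAM5	5124_69	inflammatory bowel disease	1	1262	0.029		0.305	0.034	7.45E-19		binary
ICAM5	5124_69	LDL	3	2426	0.029	Down	-0.012	0.003	7.95E-06	1	continuous
IL1RL1	4234_8	inflammatory bowel disease	1	18372	0.06		0.138	0.015	2.43E-20		binary
IL1RL1	4234_8	triglycerides	2	9434	0.06	Down	0.01	0.002	1.10E-06	0	continuous
MAPK3	2855_49	body mass index	1	822	-0.223		0.078	0.008	1.31E-20		continuous
MAPK3	2855_49	triglycerides	2	413	-0.223	Down	0.028	0.006	8.52E-06	0	continuous
MAPK3	2855_49	type II diabetes	2	413	-0.223		0.081	0.017	1.03E-06		binary
MAPKAPK2	3820_68	inflammatory bowel disease	1	376	-0.187		-0.313	0.064	1.00E-06		binary
MRC2	3041_55	diastolic blood pressure	3	169	0.06	Up	0.057	0.01	4.73E-09	1	continuous
PDE5A	16805_5	body mass index	2	241	-0.155		-0.052	0.01	3.41E-07		continuous
PDE5A	16805_5	coronary artery disease	2	237	-0.155	Up	0.15	0.029	1.60E-07	1	binary
PDE5A	16805_5	diastolic blood pressure	2	237	-0.155	Up	0.064	0.01	1.56E-11	1	continuous
PRKCB	5475_10	body mass index	2	36	-0.352		-0.157	0.031	6.63E-07		continuous
SPINT2	2843_13	heart rate	3	2412	-0.052		0.017	0.004	4.61E-06		continuous
SPINT2	2843_13	prostate cancer	2	3601	-0.052		0.094	0.012	1.93E-15		binary
SPON1	4297_62	diastolic blood pressure	2	638	0.063	Up	0.026	0.005	9.12E-07	1	continuous
SPON1	4297_62	heart rate	2	638	0.063		0.049	0.007	2.59E-13		continuous
THBS2	3339_33	diastolic blood pressure	4	1504	0.143	Up	-0.016	0.004	8.75E-06	0	continuous
TIE1	2844_53	diastolic blood pressure	1	575	-0.054	Up	0.063	0.009	4.83E-13	1	continuous
TIE1	2844_53	HDL	1	575	-0.054	Up	-0.036	0.008	2.33E-06	0	continuous
TIE1	2844_53	heart rate	1	575	-0.054		0.045	0.011	2.44E-05		continuous
TIE1	2844_53	systolic blood pressure	1	575	-0.054	Up	0.068	0.009	2.26E-15	1	continuous
YWHAB	14156_33	body mass index	2	195	-0.168		0.057	0.011	2.16E-07		continuous
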