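label	group	p_gc	t_min	t_opt	t_max	observed_min	observed_opt	observed_max	n_clones	genome_derived
Ced_A01	TCMS	54.69	14	31	39
PHF_A45_G13	TCMS	54.94	15	32	40			50
PHF_HY5ArA02	TCMS	54.63	14	30	39			80
PHF_2A-A13-I03	TCMS	54.93	15	32	40			12
PHF_2HY5ArE02	LCMS	52.25	4	19	27			15
PHF_2AarcF09	LCMS	52.75	6	21	30			10
13-A03_K23	LCMS	52.50	5	20	29			7
LC1022a1	LCMS	53.00	7	22	31
LC1149a56	LCMS	53.25	8	24	32
LC_AR37	LCMS	51.88	2	17	25
LC1231a51	LCMS	52.70	6	21	30
Methanosaeta_harundinacea_6Ac	Methanosarcinales	57.75	28	46	54	25	37	45
Methanothrix_thermophila	Methanosarcinales	58.88	33	52	60		55			yes
PHF_2CarcG12	MG-II	54.12	12	28	36			4
PHF_13A05_G23	MG-II	57.08	25	43	51			3
LC_FS243A20	MG-II	55.63	18	35	44
PHF_2CA44_G23	MG-II	54.75	15	31	40			1
PHF_13A48_A13	Thermoplasmatales	55.98	20	37	46			1
PHF_2AarcE10	Unknown-deep-sea-vent	52.38	4	19	28			1
PHF_A16_C21	SAGMEG	61.25	43	63	71			3
PHF_2CA32_019	SAGMEG	61.62	45	65	73			1
PHF_2CarcH09	SAGMEG	62.75	50	71	79			4
PHF_2HY7ArH02	SAGMEG	62.24	47	68	76			1
3H3M_ARC52	SAGMEG	62.25	47	68	76
ODP1251A1.27	SAGMEG	61.38	44	64	72
CK0606_Mud_MAS4A10	SAGMEG	63.00	51	72	80
PHF_A40_C15	Thermococcales	65.75	63	86	93			12
Thermococcus_litoralis_DSM5473	Thermococcales	65.87	63	86	94	55	88	98
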