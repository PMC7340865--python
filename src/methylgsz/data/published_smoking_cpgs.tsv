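probe_id	effect	se	p	fdr	gene_or_island	region	chromosome	in_reduced_model
cg20295214	0.03	0.005	9.53e-9	1.84e-4	AVPR1B	Body	1	0
cg08709672	0.02	0.004	3.21e-6	2.82e-2	AVPR1B	5'UTR;1stExon	1	0
cg09935388	0.06	0.009	9.87e-10	2.65e-5	GFI1	Body	1	0
cg18316974	0.03	0.006	7.64e-7	8.87e-3	GFI1	Body	1	0
cg18146737	0.05	0.01	5.55e-6	4.18e-2	GFI1	Body	1	0
cg25189904	0.03	0.006	3.85e-6	3.18e-2	GNG12	TSS1500	1	0
cg21408581	0.02	0.005	2.18e-6	2.03e-2	RAB3GAP2	Body	1	1
cg08869700	0.01	0.003	2.75e-6	2.46e-2	RFX5	Body	1	0
cg13898430	0.008	0.002	5.07e-6	3.96e-2	RUNX3	TSS1500	1	0
cg04885881	0.02	0.004	1.52e-7	2.43e-3	chr1:11119030-11120634	Shelf	1	0
cg27537125	0.02	0.003	9.85e-9	1.84e-4	-	OpenSea	1	0
cg12547807	0.01	0.002	6.36e-7	7.84e-3	-	OpenSea	1	0
cg11555067	0.02	0.003	3.42e-6	2.94e-2	INPP4A	5'UTR	2	0
cg21566642	0.03	0.002	1.02e-23	2.19e-18	chr2:233283397-233285959	Island	2	1
cg01940273	0.05	0.004	2.46e-21	3.53e-16	chr2:233283397-233285959	Island	2	1
cg05951221	0.05	0.004	8.74e-19	7.51e-14	chr2:233283397-233285959	Island	2	1
cg03329539	0.02	0.003	2.71e-9	6.86e-5	chr2:233283397-233285959	Shore	2	0
cg06644428	0.06	0.01	9.64e-7	1.09e-2	chr2:233283397-233285959	Island	2	0
cg21949194	0.02	0.003	6.06e-6	4.49e-2	chr2:39351355-39351733	Shelf	2	0
cg23079012	0.02	0.003	5.43e-10	1.67e-5	-	OpenSea	2	0
cg09355027	0.02	0.004	1.43e-6	1.46e-2	-	OpenSea	2	0
cg19859270	0.03	0.004	9.59e-12	3.75e-7	GPR15	1stExon	3	1
cg24719910	0.02	0.003	5.41e-6	4.15e-2	TGFBR2	Body	3	0
cg05575921	0.10	0.006	8.53e-28	3.66e-22	AHRR	Body	5	1
cg21161138	0.04	0.004	1.09e-19	1.17e-14	AHRR	Body	5	1
cg25648203	0.04	0.004	5.82e-13	3.57e-8	AHRR	Body	5	1
cg14817490	0.05	0.005	2.01e-12	9.60e-8	AHRR	Body	5	1
cg26703534	0.03	0.003	4.53e-12	1.95e-7	AHRR	Body	5	1
cg24090911	0.03	0.005	1.38e-10	4.56e-6	AHRR	Body	5	1
cg12806681	0.04	0.006	1.44e-8	2.59e-4	AHRR	Body	5	0
cg03991871	0.05	0.009	1.12e-7	1.85e-3	AHRR	Body	5	0
cg04551776	0.02	0.004	1.68e-7	2.58e-3	AHRR	Body	5	0
cg23916896	0.05	0.009	3.73e-7	5.17e-3	AHRR	Body	5	0
cg11554391	0.02	0.004	1.21e-6	1.27e-2	AHRR	Body	5	0
cg01899089	0.02	0.003	4.16e-6	3.31e-2	AHRR	Body	5	0
cg11902777	0.05	0.009	6.94e-6	4.97e-2	AHRR	Body	5	0
cg06126421	0.06	0.007	1.04e-12	5.61e-8	-	OpenSea	6	1
cg24859433	0.03	0.004	6.12e-11	2.19e-6	-	OpenSea	6	1
cg14753356	0.02	0.003	3.15e-9	7.52e-5	-	OpenSea	6	0
cg15342087	0.02	0.003	6.49e-9	1.39e-4	-	OpenSea	6	1
cg12803068	-0.09	0.01	2.41e-7	3.45e-3	MYO1G	Body	7	0
cg04180046	-0.03	0.005	6.39e-7	7.84e-3	MYO1G	Body	7	0
cg22132788	-0.05	0.007	1.58e-6	1.58e-2	MYO1G	Body	7	0
cg07826859	0.01	0.003	1.94e-6	1.89e-2	MYO1G	TSS1500	7	0
cg21322436	0.01	0.003	4.06e-6	3.29e-2	CNTNAP2	TSS1500	7	0
cg03450842	0.01	0.003	4.42e-7	5.93e-3	ZMIZ1	5'UTR	10	0
cg01901332	0.02	0.004	1.19e-6	1.27e-2	ARRB1	Body	11	0
cg21611682	0.02	0.003	7.56e-10	2.17e-5	LRP5	Body	11	0
cg14624207	0.01	0.003	6.91e-6	4.97e-2	LRP5	Body	11	0
cg07986378	0.02	0.005	2.49e-6	2.28e-2	ETV6	Body	12	0
cg22851561	0.02	0.003	3.90e-8	6.71e-4	C14orf43	5'UTR	14	1
cg05284742	0.02	0.003	4.53e-9	1.03e-4	ITPK1	Body	14	1
cg07069636	0.01	0.002	4.82e-7	6.28e-3	chr16:30669107-30671155	Shore	16	0
cg26038589	0.03	0.006	1.17e-6	1.27e-2	CCDC55	Body	17	0
cg10385208	0.01	0.003	3.81e-6	3.18e-2	CWC25	TSS1500	17	0
cg19572487	0.02	0.004	8.07e-9	1.65e-4	RARA	5'UTR	17	0
cg03636183	0.05	0.004	1.00e-17	7.17e-13	F2RL3	Body	19	1
cg03707168	0.02	0.004	7.10e-7	8.47e-3	PPP1R15A	Body	19	0
cg17566560	0.02	0.004	2.13e-6	2.03e-2	DLGAP4	Body;5'UTR	20	0
cg23110422	0.03	0.006	1.85e-7	2.74e-3	ETS2	Body	21	0
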