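dimension	dim_weight	dim_rank	criterion	crit_weight	crit_rank	global_weight	global_rank
C1	0.1731	1	C11	0.1207	5	0.0209	24
C1	0.1731	1	C12	0.1478	4	0.0256	19
C1	0.1731	1	C13	0.1808	3	0.0313	15
C1	0.1731	1	C14	0.2663	2	0.0461	7
C1	0.1731	1	C15	0.2845	1	0.0493	4
C2	0.1461	3	C21	0.0935	4	0.0137	29
C2	0.1461	3	C22	0.2021	3	0.0295	17
C2	0.1461	3	C23	0.3253	2	0.0475	5
C2	0.1461	3	C24	0.3791	1	0.0554	2
C3	0.1284	4	C31	0.2051	3	0.0263	18
C3	0.1284	4	C32	0.3657	2	0.0469	6
C3	0.1284	4	C33	0.4292	1	0.0551	3
C4	0.1463	2	C41	0.1086	4	0.0159	27
C4	0.1463	2	C42	0.2951	3	0.0432	12
C4	0.1463	2	C43	0.3002	1	0.0439	9
C4	0.1463	2	C44	0.2961	2	0.0433	10
C5	0.1095	5	C51	0.3950	2	0.0432	11
C5	0.1095	5	C52	0.6050	1	0.0662	1
C6	0.0925	8	C61	0.1833	3	0.0170	25
C6	0.0925	8	C62	0.3376	2	0.0312	16
C6	0.0925	8	C63	0.4790	1	0.0443	8
C7	0.0973	7	C71	0.1515	4	0.0147	28
C7	0.0973	7	C72	0.1651	3	0.0161	26
C7	0.0973	7	C73	0.3578	1	0.0348	13
C7	0.0973	7	C74	0.3255	2	0.0317	14
C8	0.1069	6	C81	0.1256	5	0.0134	30
C8	0.1069	6	C82	0.2056	4	0.0220	23
C8	0.1069	6	C83	0.2095	3	0.0224	22
C8	0.1069	6	C84	0.2310	1	0.0247	20
C8	0.1069	6	C85	0.2283	2	0.0244	21
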