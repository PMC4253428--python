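cell_line	snvs	pct_snvs_germline	somatic_snvs	somatic_nonsyn_snvs	nonsense_snvs	indels	pct_indels_germline	somatic_indels	frameshift_indels	mutation_rate	mutator
CACO2	2572	98	41	24	0	51	33	12	8	6.72E-06	No
COLO205	2753	98	43	33	0	64	30	15	11	7.05E-06	No
COLO320	3813	97	86	65	4	43	53	2	2	1.21E-04	No
HCC2998	3391	78	738	569	44	52	37	16	14	5.85E-05	Yes
HCT116	3193	88	357	237	10	106	18	61	54	1.76E-04	Yes
HCT15	3959	73	1071	775	34	77	26	31	27	1.08E-05	Yes
HT29	2373	96	66	49	3	49	33	9	8	6.92E-05	No
KM12	2978	86	422	284	12	117	15	74	65	2.39E-05	Yes
LIM1215	2841	95	146	103	2	81	21	41	39	3.39E-05	Yes
LIM2405	2731	92	207	148	6	91	18	53	53	7.90E-05	Yes
LOVO	4591	88	495	352	11	130	22	82	74	1.36E-05	Yes
RKO	3500	86	482	344	15	123	16	83	75	1.62E-05	Yes
RW2982	3545	97	80	57	2	32	50	8	5	1.41E-05	No
RW7213	3763	98	62	40	0	44	48	7	1	8.12E-05	No
SKCO1	4055	96	118	79	5	43	49	5	5	1.31E-05	No
SW1116	3719	97	89	64	0	47	51	6	4	1.02E-05	No
SW403	4196	94	165	123	9	48	58	4	4	1.94E-05	No
SW48	4706	88	530	365	15	177	23	96	92	1.46E-05	Yes
SW480	2440	96	83	60	3	43	28	8	8	2.71E-05	No
SW620	2535	95	99	69	3	49	29	13	9	8.69E-05	No
SW837	3912	97	62	44	3	42	50	4	3	1.02E-05	No
SW948	2820	98	56	35	2	34	53	3	1	9.18E-06	No
T84	4089	96	118	86	2	51	51	5	2	1.94E-05	No
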