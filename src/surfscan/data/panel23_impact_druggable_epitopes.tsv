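cell_line	mutator	impact_nonsyn	impact_indels	druggable_mutations	expressed_druggable_mutations	mutated_epitopes	expressed_mutated_epitopes
CACO2	No	8	6	4	3	0	0
COLO205	No	10	11	9	2	1	0
COLO320	No	24	1	15	3	2	0
HCC2998	Yes	196	9	128	17	11	3
HCT116	Yes	81	45	66	19	7	4
HCT15	Yes	287	20	184	57	19	7
HT29	No	10	4	16	1	2	1
KM12	Yes	91	54	74	27	6	2
LIM1215	Yes	42	33	40	13	0	0
LIM2405	Yes	48	46	56	16	7	2
LOVO	Yes	160	57	69	19	8	2
RKO	Yes	131	72	95	30	7	2
RW2982	No	17	3	9	2	3	0
RW7213	No	13	4	10	2	0	0
SKCO1	No	24	3	10	3	1	0
SW1116	No	29	3	9	3	2	1
SW403	No	36	4	22	4	0	0
SW48	Yes	141	75	91	24	4	2
SW480	No	26	7	13	7	3	1
SW620	No	26	11	18	4	1	0
SW837	No	9	2	6	2	1	0
SW948	No	14	3	8	1	0	0
T84	No	27	4	15	3	1	0
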