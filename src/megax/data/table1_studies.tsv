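study_id	n_control	n_case	country	study_age_years	organism
GSE84784	9	9	Luxembourg	2	Homo sapiens
GSE67061	8	69	China	3	Homo sapiens
GSE30219	14	61	France	5	Homo sapiens
GSE33479	27	14	USA	5	Homo sapiens
GSE32036	59	12	USA	7	Homo sapiens
GSE19188	65	27	Netherlands	9	Homo sapiens
GSE11969	5	35	Japan	10	Homo sapiens
GSE2088	30	48	Japan	10	Homo sapiens
GSE12428	28	34	Netherlands	11	Homo sapiens
GSE6044	5	14	Germany	13	Homo sapiens
GSE1987	7	17	Israel	15	Homo sapiens
GSE12472	28	35	Netherlands	10	Homo sapiens
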