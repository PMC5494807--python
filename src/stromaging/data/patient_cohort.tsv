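patient_id	age_years	group	er	pr	her2	tumour_type	tumour_grade	max_size_cm	pT	pN
6	27	young	Neg	Neg	Neg	Ductal	3	2.3	2	0
5	30	young	Neg	Neg	Neg	Ductal	3	2.5	2	0
7	32	young	Neg	Neg	Neg	Ductal	3	2.2	2	0
1	33	young	Neg	Neg	Neg	Ductal	3	2.8	2	0
3	39	young	Neg	Neg	Neg	Ductal	3	3.0	2	0
2	43	young	Neg	Neg	Neg	Ductal	3	3.0	2	2a
4	44	young	Neg	Neg	Neg	Ductal	3	2.8	2	0
8	44	young	Neg	Neg	Neg	Ductal	3	3.5	2	0
9	44	young	Neg	Neg	Neg	Ductal	3	3.0	2	0
12	80	old	Neg	Neg	Neg	Ductal	3	4.0	2	0
16	82	old	Neg	Neg	Neg	Ductal	3	3.5	2	0
17	82	old	Neg	Neg	Neg	Ductal	3	1.5	1c	0
13	82	old	Neg	Neg	Neg	Ductal	2	3.0	2	3a
15	83	old	Neg	Neg	Neg	Ductal	3	3.8	2	1a
10	83	old	Neg	Neg	Neg	Ductal	3	3.2	2	0
11	86	old	Neg	Neg	Neg	Ductal	3	3.0	2	0
14	87	old	Neg	Neg	Neg	Ductal	3	2.0	1c	0
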