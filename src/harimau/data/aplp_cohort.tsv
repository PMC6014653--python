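# Worked-example APLP cohort (published screening outcomes transcribed as
# genotypes over the demo panel; empty genotype = amplification failure).
lab_no	individual	sample	period	aplp_published	genotypes
1	No.1	Right temporal bone	Metal	E	489=G;16390=T;8701=T
2	No.2	Maxilla, Right, M2	Metal	N.D.	
3	No.3	Mandible, Right, M1	Metal	N.D.	
4	No.4	Maxilla, Right, M1	Metal	N.D.	
5	No.4	Right temporal bone	Metal	N.D.	
6	No.8	Mandible, Right, M2	Metal	N.D.	
7	No.8	Maxilla, Right, M3	Metal	N.D.	
8	No.9	Mandible, Right, M2	Metal	N.D.	
9	No.9	Left temporal bone	Metal	B4a	8701=C;12705=T;16217=A;16261=G;489=A
10	No.10	Maxilla, Right, M1	Metal	N.D.	
11	No.11	Maxilla, Right, M3	Metal	N.D.	
12	No.11	Left temporal bone	Metal	N.D.	
13	No.12	Mandible, Left, M3	Metal	N.D.	
14	No.12	Left temporal bone	Metal	N9a	8701=C;5417=C;12358=G;489=A
15	No.14	Mandible, Left, C	Metal	M7	489=G;9824=G;8701=T
15	No.19	Maxilla, Right, M3	Metal	N.D.	
17	No.21	Mandible, Left, M2	Metal	N.D.	
18	No.23	Mandible, Right, M2	Metal	N.D.	
19	No.23	Left temporal bone	Metal	Y2	8701=C;5417=C;6941=T;489=A
20	No.24	Mandible, Right, M2	Metal	N.D.	
21	No.24	Right temporal bone	Metal	Y2	8701=C;5417=C;6941=T;489=A
22	No.25	Right temporal bone	Metal	N	8701=C;489=A
23	No.26	Left temporal bone	Neolithic	R	8701=C;12705=T;489=A
24	No.27	Mandible, Right, M3	Metal	N.D.	
25	No.27	Right temporal bone	Metal	M	489=G;8701=T
26	No.36	Maxilla, Right, M3	Neolithic	N.D.	
27	No.36	Left temporal bone	Neolithic	N.D.	
28	No.38	Right temporal bone	Neolithic	R	8701=C;12705=T;489=A
29	No.39	Maxilla, Right, M3	Neolithic	N.D.	
30	No.42	Right temporal bone	Metal	E	489=G;16390=T;8701=T
31	No.49	Right temporal bone	Metal	N.D.	
32	No.57	Right temporal bone	Metal	R	8701=C;12705=T;489=A
33	No.60	Mandible, Right, M2	Metal	B4c	8701=C;12705=T;16217=A;3497=G;489=A
34	No.74	Maxilla, Left, M3	Pre-Neolithic	N.D.	
35	No.79	Maxilla, Right, M2	Pre-Neolithic	N.D.	
36	No.79	Right temporal bone	Pre-Neolithic	N.D.	
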