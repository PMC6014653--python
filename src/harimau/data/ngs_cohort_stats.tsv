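# Worked-example per-library sequencing statistics and haplogroup calls
# (published cohort values transcribed; empty = not reported).
individual	sample	mapq20_reads	coverage_pct	avg_depth	hg_manual	hg_aplp	contamination	additional_variants
No.1	Right temporal bone	10133	99.99	47.2	E1a1a1a	E	0% [0–0.5%]	None
No.4	Maxilla, Right, M1	2729	96.99	9.3	E1a1a1	N.D.	0% [0–1%]	C10132T
No.4	Right temporal bone	26			N.D.	N.D.		
No.9	Left temporal bone	3332	99.94	12.9	B4a1a	B4a	6.5% [4.5–8.5%]	A200G,GCA513G,T11830C,CAA16179C
No.11	Left temporal bone	60			N.D.	N.D.		
No.12	Left temporal bone	67			N.D.	N9a		
No.14	Mandible, Left, C	288	71.19	1.4	(M7b1a)	M7		
No.23	Left temporal bone	6688	99.98	30.7	Y2a1	Y2	1.5% [0.5–2.5%]	None
No.24	Right temporal bone	6775	99.98	27.5	Y2a1	Y2	1.5% [0.5–2.5%]	None
No.25	Right temporal bone	1785	99.40	7.1	F1a1a1	N	0% [0–0.5%]	GCA513G
No.26	Left temporal bone	21376	100.00	109.1	R	R	2% [1–3%]	C150T,A189G,T310TC,T450C,A3397G,G3483A,C3600A,A5484G,C6164T,A7271G,T9833C,G9966A,C10777T,G11150A,T14178C,T14311C,A15766G,T16304C
No.27	Right temporal bone	10381	99.98	40.3	M	M	0% [0–0.5%]	C151T,T152C,T310TC,GCA513G,C3817T,T4336C,T4823C,G8592A,A9285G,G11176A,C12378T,G15172A,T16229C,C16294T,T16311C
No.36	Left temporal bone	152			N.D.	N.D.		
No.38	Right temporal bone	4784	99.96	19.3	B4c1b2a2	R	0% [0–0.5%]	None
No.42	Right temporal bone	16614	100.00	88.8	E1a1a1a	E	0% [0–0.5%]	A302AC,T310TC
No.49	Right temporal bone	40			N.D.	N.D.		
No.57	Right temporal bone	850			N.D.	R		
No.60	Mandible, Right, M2	8273	99.95	35.7	B4c1b2a2	B4c	0% [0–0.5%]	C146T,A302ACC,A16183C
No.79	Maxilla, Right, M2	0			N.D.	N.D.		
No.79	Right temporal bone	420			N.D.	N.D.		
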