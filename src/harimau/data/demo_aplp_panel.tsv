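# Demo multiplex APLP panel: one diagnostic site per demo-tree node,
# plus synthetic indel and 9-bp repeat records.
position	ref	alt	haplogroup	kind
8701	T	C	N	SNP
12705	C	T	R	SNP
489	A	G	M	SNP
16217	G	A	B4	SNP
16261	A	G	B4a	SNP
14022	C	T	B4a1	SNP
6719	G	A	B4a1a	SNP
3497	A	G	B4c	SNP
5465	A	G	B4c1b2a2	SNP
6962	C	T	F1	SNP
6392	A	G	F1a	SNP
1824	G	A	F1a1a	SNP
2667	A	G	F1a1a1	SNP
9824	A	G	M7	SNP
4048	A	G	M7b	SNP
12811	T	C	M7b1a	SNP
5417	T	C	N9	SNP
12358	A	G	N9a	SNP
6941	C	T	Y2	SNP
3399	G	A	Y2a1	SNP
16390	C	T	E	SNP
10834	T	C	E1	SNP
5301	A	G	E1a	SNP
7598	C	T	E1a1	SNP
14577	A	G	E1a1a	SNP
2397	C	T	E1a1a1	SNP
13254	A	G	E1a1a1a	SNP
249	ins	del	F1	indel
8281	ins	del	B4	indel
960	del	ins	E1	indel
8289	rep2	rep1	B4	repeat
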