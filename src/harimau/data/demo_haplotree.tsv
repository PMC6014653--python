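# Demo haplotree for the bundled synthetic reference (root = reference state).
# Macrohaplogroup N/R/M diagnostic positions are published coordinates;
# all other defining variants are synthetic placeholders.
node	parent	variants
MT		
N	MT	T8701C,A9540G,G10398A,C10873T,C15301T
R	N	C12705T,C16223T
M	MT	A489G,G10400A,C14783T,C15043T
B4	R	G16217A
B4a	B4	A16261G
B4a1	B4a	C14022T
B4a1a	B4a1	G6719A
B4c	B4	A3497G
B4c1b2a2	B4c	A5465G,C11708T
F1	R	C6962T
F1a	F1	A6392G
F1a1a	F1a	G1824A
F1a1a1	F1a1a	A2667G
M7	M	A9824G
M7b	M7	A4048G
M7b1a	M7b	T12811C
N9	N	T5417C
N9a	N9	A12358G
Y2	N9	C6941T
Y2a1	Y2	G3399A
E	M	C16390T
E1	E	T10834C
E1a	E1	A5301G
E1a1	E1a	C7598T
E1a1a	E1a1	A14577G
E1a1a1	E1a1a	C2397T
E1a1a1a	E1a1a1	A13254G
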