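#pseudo=0.05
aa5	aa35	A	C	G	U
A	D	0.15	0.25	0.35	0.25
G	D	0.15	0.2	0.45	0.2
G	N	0.4	0.2	0.2	0.2
N	D	0.08	0.3	0.07	0.55
N	G	0.15	0.35	0.15	0.35
N	N	0.1	0.48	0.07	0.35
N	S	0.1	0.52	0.08	0.3
N	T	0.12	0.4	0.1	0.38
P	D	0.15	0.25	0.35	0.25
S	D	0.1	0.12	0.66	0.12
S	N	0.65	0.12	0.11	0.12
S	S	0.35	0.25	0.15	0.25
S	T	0.42	0.2	0.18	0.2
T	D	0.1	0.1	0.7	0.1
T	N	0.7	0.1	0.1	0.1
T	T	0.45	0.18	0.19	0.18
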