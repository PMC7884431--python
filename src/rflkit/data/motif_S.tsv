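#name=S
#threshold=13
residue	1	2	3	4	5	6	7	8	9	10	11	12	13	14	15	16	17	18	19	20	21	22	23	24	25	26	27	28	29	30	31
A	-1	-1	-1	-1	0.25	-1	-1	-1	0.75	-1	-1	-1	1.5	0.75	-1	-1	-1	-1	1.5	-1	1.5	-1	-1	-1	-1	-1	-1	-1	-1	0.75	0.25
C	-1	-1	-1	-1	0.25	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	0.25
D	-1	-1	-1	-1	0.25	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	1.5	1.5	-1	-1	-1	-1	-1	-1	0.75	-1	-1	-1	-1	-1	0.25
E	-1	-1	-1	-1	0.25	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	0.75	0.75	-1	-1	-1	-1	-1	-1	1.5	-1	-1	-1	-1	-1	0.25
F	-1	-1	1.5	-1	0.25	-1	-1	-1	-1	0.75	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	1.5	-1	-1	-1	-1	-1	-1	-1	0.25
G	-1	-1	-1	-1	0.25	-1	-1	-1	1.5	-1	-1	-1	0.75	1.5	-1	-1	-1	-1	0.75	-1	0.75	-1	-1	-1	-1	-1	-1	-1	-1	1.5	0.25
H	-1	-1	-1	-1	0.25	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	0.25
I	0.75	-1	-1	-1	0.25	0.75	1.5	-1	-1	-1	0.75	-1	-1	-1	0.75	0.75	-1	-1	-1	0.75	-1	0.75	-1	-1	-1	0.75	-1	0.75	-1	-1	0.25
K	-1	-1	-1	-1	0.25	-1	-1	1.5	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	0.75	-1	-1	-1	-1	1.5	-1	0.25
L	0.75	-1	-1	-1	0.25	0.75	0.75	-1	-1	-1	0.75	-1	-1	-1	1.5	0.75	-1	-1	-1	1.5	-1	1.5	-1	-1	-1	0.75	-1	0.75	-1	-1	0.25
M	0.75	-1	-1	-1	0.25	1.5	0.75	-1	-1	-1	0.75	-1	-1	-1	0.75	0.75	-1	-1	-1	0.75	-1	0.75	-1	-1	-1	1.5	-1	0.75	-1	-1	0.25
N	-1	-1	-1	1.5	0.25	-1	-1	-1	-1	-1	-1	0.75	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	0.75	-1	-1	-1	0.25
P	-1	-1	-1	-1	0.25	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	0.25
Q	-1	-1	-1	0.75	0.25	-1	-1	-1	-1	-1	-1	1.5	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	1.5	-1	-1	-1	0.25
R	-1	-1	-1	-1	0.25	-1	-1	0.75	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	1.5	-1	-1	-1	-1	0.75	-1	0.25
S	-1	0.75	-1	-1	0.25	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	0.25
T	-1	1.5	-1	-1	0.25	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	0.25
V	1.5	-1	-1	-1	0.25	0.75	0.75	-1	-1	-1	1.5	-1	-1	-1	0.75	1.5	-1	-1	-1	0.75	-1	0.75	-1	-1	-1	0.75	-1	1.5	-1	-1	0.25
W	-1	-1	0.75	-1	0.25	-1	-1	-1	-1	0.75	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	0.75	-1	-1	-1	-1	-1	-1	-1	0.25
Y	-1	-1	0.75	-1	0.25	-1	-1	-1	-1	1.5	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	-1	0.75	-1	-1	-1	-1	-1	-1	-1	0.25
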