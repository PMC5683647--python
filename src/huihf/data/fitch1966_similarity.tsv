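	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	1	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
C	0	1	0	0	1	0	0	1	0	1	1	0	0	0	0	0	0	1	1	1
D	0	0	1	1	0	0	1	0	1	0	0	1	0	1	1	1	1	0	0	0
E	0	0	1	1	0	0	1	0	1	0	0	1	0	1	1	1	1	0	0	0
F	0	1	0	0	1	0	0	1	0	1	1	0	0	0	0	0	0	1	1	1
G	1	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0
H	0	0	1	1	0	0	1	0	1	0	0	1	0	1	1	1	1	0	0	0
I	0	1	0	0	1	0	0	1	0	1	1	0	0	0	0	0	0	1	1	1
K	0	0	1	1	0	0	1	0	1	0	0	1	0	1	1	1	1	0	0	0
L	0	1	0	0	1	0	0	1	0	1	1	0	0	0	0	0	0	1	1	1
M	0	1	0	0	1	0	0	1	0	1	1	0	0	0	0	0	0	1	1	1
N	0	0	1	1	0	0	1	0	1	0	0	1	0	1	1	1	1	0	0	0
P	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0
Q	0	0	1	1	0	0	1	0	1	0	0	1	0	1	1	1	1	0	0	0
R	0	0	1	1	0	0	1	0	1	0	0	1	0	1	1	1	1	0	0	0
S	0	0	1	1	0	0	1	0	1	0	0	1	0	1	1	1	1	0	0	0
T	0	0	1	1	0	0	1	0	1	0	0	1	0	1	1	1	1	0	0	0
V	0	1	0	0	1	0	0	1	0	1	1	0	0	0	0	0	0	1	1	1
W	0	1	0	0	1	0	0	1	0	1	1	0	0	0	0	0	0	1	1	1
Y	0	1	0	0	1	0	0	1	0	1	1	0	0	0	0	0	0	1	1	1
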