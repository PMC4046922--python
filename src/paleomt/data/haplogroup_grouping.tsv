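raw_label	category
AS	AS
AF	AF
H	H
HV	HV
HV0	HV0
preV	HV0
V	HV0
R0	R0
preHV	R0
K	K
U5	U5
J	J
T	T
T1	T
T2	T
N*	N*
N1	N1
N1a	N1
N1b	N1
N2	N2
U7	U7
U3	U3
U1	U1
U6	U6
U4	U4
U2	U2
U8	U+
U9	U+
U+	U+
R1	R+
R2	R+
R+	R+
X	X
W	W
U*	U*
I	I
L	AF
L0	AF
L1	AF
L2	AF
L3	AF
L4	AF
L5	AF
L6	AF
L7	AF
M1	AF
A	AS
B	AS
C	AS
D	AS
E	AS
F	AS
G	AS
M	AS
M*	AS
N9	AS
R5	AS
R9	AS
Q	AS
Y	AS
Z	AS
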