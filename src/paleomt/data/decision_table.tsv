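label	priority	snp_conditions	motif_conditions
L3	1	10873=C	16223T
N*	2	12705=T
K	3	12308=G;10550=G	16311C
U*	4	12308=G	16311C
H	5	7028=C
HV	6	7028=T;14766=C
R0	7	7028=T;12308=A;12705=C	16293C
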