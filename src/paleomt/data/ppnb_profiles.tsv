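site	sample_id	motif	window_lo	window_hi	snp_typings	expected_haplogroup
Tell Halula	H3	16293C	16256	16369	7028:T:1,12308:A:1,14766:T:1,10873:T:1,10550:G:0,12705:C:1	R0
Tell Halula	H4	16311C	16126	16369	7028:T:1,12308:G:1,10550:G:1	K
Tell Halula	H7	16311C	16126	16369	7028:T:1,12308:G:1,10550:G:1	K
Tell Halula	H8	16223T	16126	16369	7028:T:1,12308:A:1,14766:T:0,10873:C:1,10550:A:1,10398:A:1,10400:C:1	L3
Tell Halula	H70	16356C	16126	16369	7028:T:1,12308:A:1,14766:T:1,10873:T:1,10550:A:1,12705:T:1,4646:T:1	N*
Tell Halula	H68	16294T	16256	16369	7028:C:1	H
Tell Halula	H53	CRS	16126	16256	7028:T:0,12308:A:0,12705:C:0	HV
Tell Halula	H49	16256T	16126	16369	7028:C:1,12308:A:0,10550:A:0,12705:C:0	H
Tell Halula	H25	16224C 16311C	16126	16369	7028:T:0,12308:G:1,10550:G:1	K
Tell Halula	H28	16311C	16256	16369	7028:T:0,12308:G:1,10550:A:1	U*
Tell Ramad	R64-4II	16293C	16256	16369	7028:T:1,12308:A:1,14766:T:1,10550:A:1,12705:C:1	R0
Tell Ramad	R65-14	16224C 16311C 16366T	16126	16369	7028:T:0,12308:G:1,14766:T:0,10550:G:1	K
Tell Ramad	R69(2)	16293C	16126	16369	7028:T:1,12308:A:1,10873:T:1,12705:C:1	R0
Tell Ramad	R65-C8-SEB	16224C 16311C 16366T	16126	16369	7028:T:0,12308:G:1	K
Tell Ramad	R65-1S	16224C 16311C 16366T	16126	16369	7028:T:0,12308:G:0,10550:G:1	K
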