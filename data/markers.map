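# chromosome name cM bp het   ('*' flags the focal variant)
14	D14S1065	0.000000	72800000	0.630000
14	D14S258	1.500000	73700000	0.650000
14	D14S1028	3.000000	74500000	0.670000
14	D14S1047	5.000000	75600000	0.690000
14	D14S61	5.900000	76200000	0.710000
14*	TGFB3_c.787G>C	6.100000	76447000
14	D14S270	7.130000	77520000	0.730000
14	D14S983	9.540000	78640000	0.750000
14	D14S74	11.000000	79600000	0.770000
14	D14S287	12.500000	80500000	0.790000
14	D14S1037	14.000000	81400000	0.810000
14	D14S1044	15.500000	82300000	0.830000
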