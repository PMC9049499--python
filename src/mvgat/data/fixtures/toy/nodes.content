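n00	1.500000	-0.200000	0.100000	0.400000	A
n01	2.200000	0.500000	-0.300000	0.000000	A
n02	1.800000	0.100000	0.400000	-0.400000	A
n03	2.500000	-0.300000	0.000000	0.300000	A
n04	2.100000	0.400000	-0.400000	-0.100000	A
n05	1.700000	0.000000	0.300000	-0.500000	A
n06	2.400000	-0.400000	-0.100000	0.200000	A
n07	2.000000	0.300000	-0.500000	-0.200000	A
n08	1.600000	-0.100000	0.200000	0.500000	A
n09	2.300000	-0.500000	-0.200000	0.100000	A
n10	1.900000	0.200000	0.500000	-0.300000	A
n11	1.500000	-0.200000	0.100000	0.400000	A
n12	2.200000	0.500000	-0.300000	0.000000	A
n13	1.800000	0.100000	0.400000	-0.400000	A
n14	2.500000	-0.300000	0.000000	0.300000	A
n15	0.100000	2.400000	-0.400000	-0.100000	B
n16	-0.300000	2.000000	0.300000	-0.500000	B
n17	0.400000	1.600000	-0.100000	0.200000	B
n18	0.000000	2.300000	-0.500000	-0.200000	B
n19	-0.400000	1.900000	0.200000	0.500000	B
n20	0.300000	1.500000	-0.200000	0.100000	B
n21	-0.100000	2.200000	0.500000	-0.300000	B
n22	-0.500000	1.800000	0.100000	0.400000	B
n23	0.200000	2.500000	-0.300000	0.000000	B
n24	-0.200000	2.100000	0.400000	-0.400000	B
n25	0.500000	1.700000	0.000000	0.300000	B
n26	0.100000	2.400000	-0.400000	-0.100000	B
n27	-0.300000	2.000000	0.300000	-0.500000	B
n28	0.400000	1.600000	-0.100000	0.200000	B
n29	0.000000	2.300000	-0.500000	-0.200000	B
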