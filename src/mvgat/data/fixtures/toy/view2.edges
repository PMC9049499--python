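n00	n03
n00	n08
n00	n11
n01	n04
n01	n07
n01	n12
n02	n05
n02	n10
n02	n13
n03	n06
n03	n08
n03	n09
n03	n11
n03	n14
n04	n07
n04	n12
n05	n10
n05	n13
n06	n09
n06	n14
n07	n12
n08	n11
n09	n14
n10	n13
n15	n18
n15	n23
n15	n26
n15	n29
n16	n21
n16	n24
n16	n27
n17	n20
n17	n25
n17	n28
n18	n26
n18	n29
n19	n21
n19	n22
n19	n23
n20	n23
n20	n25
n20	n28
n21	n22
n21	n24
n21	n27
n22	n23
n23	n26
n24	n27
n25	n28
n26	n29
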