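n00	n01
n00	n02
n00	n03
n00	n04
n00	n05
n00	n06
n00	n07
n00	n08
n00	n09
n00	n10
n00	n11
n00	n12
n00	n13
n00	n14
n01	n02
n01	n03
n01	n04
n01	n05
n01	n06
n01	n07
n01	n08
n01	n09
n01	n10
n01	n11
n01	n12
n01	n13
n01	n14
n02	n03
n02	n04
n02	n05
n02	n06
n02	n07
n02	n08
n02	n09
n02	n10
n02	n11
n02	n12
n02	n13
n02	n14
n03	n04
n03	n05
n03	n06
n03	n07
n03	n08
n03	n09
n03	n10
n03	n11
n03	n12
n03	n13
n03	n14
n04	n05
n04	n06
n04	n07
n04	n08
n04	n09
n04	n10
n04	n11
n04	n12
n04	n13
n04	n14
n05	n06
n05	n07
n05	n08
n05	n09
n05	n10
n05	n11
n05	n12
n05	n13
n05	n14
n06	n07
n06	n08
n06	n09
n06	n10
n06	n11
n06	n12
n06	n13
n06	n14
n07	n08
n07	n09
n07	n10
n07	n11
n07	n12
n07	n13
n07	n14
n08	n09
n08	n10
n08	n11
n08	n12
n08	n13
n08	n14
n09	n10
n09	n11
n09	n12
n09	n13
n09	n14
n10	n11
n10	n12
n10	n13
n10	n14
n11	n12
n11	n13
n11	n14
n12	n13
n12	n14
n13	n14
n15	n16
n15	n17
n15	n18
n15	n19
n15	n20
n15	n21
n15	n22
n15	n23
n15	n24
n15	n25
n15	n26
n15	n27
n15	n28
n15	n29
n16	n17
n16	n18
n16	n19
n16	n20
n16	n21
n16	n22
n16	n23
n16	n24
n16	n25
n16	n26
n16	n27
n16	n28
n16	n29
n17	n18
n17	n19
n17	n20
n17	n21
n17	n22
n17	n23
n17	n24
n17	n25
n17	n26
n17	n27
n17	n28
n17	n29
n18	n19
n18	n20
n18	n21
n18	n22
n18	n23
n18	n24
n18	n25
n18	n26
n18	n27
n18	n28
n18	n29
n19	n20
n19	n21
n19	n22
n19	n23
n19	n24
n19	n25
n19	n26
n19	n27
n19	n28
n19	n29
n20	n21
n20	n22
n20	n23
n20	n24
n20	n25
n20	n26
n20	n27
n20	n28
n20	n29
n21	n22
n21	n23
n21	n24
n21	n25
n21	n26
n21	n27
n21	n28
n21	n29
n22	n23
n22	n24
n22	n25
n22	n26
n22	n27
n22	n28
n22	n29
n23	n24
n23	n25
n23	n26
n23	n27
n23	n28
n23	n29
n24	n25
n24	n26
n24	n27
n24	n28
n24	n29
n25	n26
n25	n27
n25	n28
n25	n29
n26	n27
n26	n28
n26	n29
n27	n28
n27	n29
n28	n29
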