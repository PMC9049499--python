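n00
n01
n02
n03
n04
n05
n06
n07
n08
n09
n10
n11
n12
n13
n14
n15
n16
n17
n18
n19
n20
n21
n22
n23
n24
n25
n26
n27
n28
n29
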