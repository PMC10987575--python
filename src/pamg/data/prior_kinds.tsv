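kind
ppa
phoD
phnD
pstS
yjbB
phoB
phoA
phoH
phoN
phoX
aphA
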