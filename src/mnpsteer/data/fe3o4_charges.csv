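atom,q_e
Fe_tetrahedral,1.68
Fe_octahedral,1.60
O,-1.22
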