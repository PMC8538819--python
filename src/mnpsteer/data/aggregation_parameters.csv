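parameter,nominal,low,high
diameter_um,0.5,0.5,1
time_s,1,1,30
current_A,3,0.5,3
density_uL,30,10,30
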