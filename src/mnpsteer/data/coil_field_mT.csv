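current_A,1,2.5,5,7.5,10
1,17,8,4.5,2.3,1.6
2,28,13,10,5.5,3.5
3,43,25.5,13,7,4.5
4,53,25,12.5,7.8,5.1
5,58,34.5,16,11,7.2
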