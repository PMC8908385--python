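2,2,2,1,1
toy,,,BEL,LAN
Ind,Pop,L1,,L2,
I1,BEL,120,124,130,130
I2,LAN,120,120,0,0
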