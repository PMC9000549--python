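group,pka
Nterm,9.69
Cterm,2.34
K,10.53
R,12.48
H,6.00
D,3.65
E,4.25
C,8.18
Y,10.07
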