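age_lo,age_hi,weight
0,45,0.07
45,55,0.12
55,65,0.23
65,75,0.29
75,90,0.29
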