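age_lo,age_hi,weight
0,5,0.12
5,10,0.10
10,15,0.09
15,20,0.09
20,25,0.08
25,30,0.08
30,35,0.06
35,40,0.06
40,45,0.06
45,50,0.06
50,55,0.05
55,60,0.04
60,65,0.04
65,70,0.03
70,75,0.02
75,80,0.01
80,85,0.005
85,90,0.005
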