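group_id,age_lo,age_hi,n_male,n_female
1,6,10,7,7
2,11,15,3,2
3,16,20,1,2
4,21,25,6,16
5,26,30,5,7
6,31,35,4,4
7,36,40,3,7
8,41,45,4,2
9,46,50,3,6
10,51,57,3,7
11,58,65,3,5
12,66,70,2,5
13,71,75,5,10
14,76,79,2,2
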