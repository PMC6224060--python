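node_i,node_j,frequency
31,78,14
29,76,13
30,77,13
22,31,12
69,78,12
28,75,11
54,64,11
1,48,10
36,83,8
47,94,8
75,76,7
77,78,7
30,31,7
48,75,7
22,69,6
24,36,5
22,78,5
31,69,4
31,77,4
28,29,4
23,47,3
1,28,3
29,75,3
21,22,2
28,48,2
30,78,2
22,77,1
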