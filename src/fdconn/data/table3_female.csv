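node_i,node_j,frequency
22,31,14
31,78,14
29,76,13
1,48,11
69,78,12
30,77,10
36,83,9
22,78,9
47,94,9
30,31,8
28,75,8
75,76,7
48,75,7
77,78,7
30,78,6
31,69,6
1,28,5
22,69,5
28,29,3
28,76,2
69,70,1
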