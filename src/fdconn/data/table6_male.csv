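node,ci
31,1.00
78,0.98
75,0.73
77,0.66
22,0.63
28,0.56
76,0.56
30,0.54
69,0.54
29,0.49
48,0.49
36,0.41
47,0.39
64,0.39
83,0.39
1,0.37
54,0.37
40,0.27
94,0.24
87,0.22
7,0.20
24,0.20
17,0.17
23,0.15
73,0.12
79,0.12
26,0.10
32,0.10
70,0.10
50,0.07
65,0.07
71,0.07
3,0.05
21,0.05
45,0.05
51,0.05
57,0.05
67,0.05
68,0.05
8,0.02
10,0.02
12,0.02
39,0.02
42,0.02
46,0.02
55,0.02
59,0.02
93,0.02
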