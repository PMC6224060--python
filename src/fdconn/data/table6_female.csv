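node,ci
78,1
31,0.88
22,0.63
69,0.53
48,0.51
30,0.49
76,0.49
75,0.47
1,0.39
28,0.39
77,0.37
29,0.35
47,0.33
83,0.31
94,0.27
36,0.24
64,0.22
87,0.22
54,0.2
70,0.2
17,0.18
23,0.16
7,0.14
40,0.14
13,0.1
79,0.1
10,0.08
24,0.08
71,0.08
32,0.06
43,0.06
46,0.06
12,0.04
25,0.04
42,0.04
67,0.04
68,0.04
72,0.04
80,0.04
86,0.04
18,0.02
20,0.02
21,0.02
26,0.02
27,0.02
39,0.02
45,0.02
55,0.02
57,0.02
59,0.02
63,0.02
66,0.02
73,0.02
74,0.02
90,0.02
93,0.02
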