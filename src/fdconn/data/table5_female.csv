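node_i,node_j,F1,F2,F3,F4,F5,F6,F7,F8,F9,F10,F11,F12,F13,F14
22,31,0.51,0.27,0.27,0.26,0.20,0.26,0.28,0.21,0.11,0.26,0.28,0.39,0.22,0.21
31,78,0.91,0.45,0.49,0.48,0.60,0.50,0.44,0.26,0.13,0.44,0.62,0.55,0.34,0.33
29,76,1,0.20,0.21,0.15,0.48,0.28,0.29,0,0.05,0.25,0.58,0.45,0.16,0.16
1,48,0.67,0,0,0.21,0.39,0.31,0.31,0.19,0.09,0.26,0.38,0.37,0.23,0.24
69,78,0,0.26,0.34,0.22,0.25,0.32,0.26,0,0.09,0,0.34,0.34,0.21,0.24
30,77,0.84,0.23,0,0.22,0.39,0,0.20,0.14,0,0.34,0.34,0.43,0.18,0
36,83,0.54,0,0.34,0.25,0.29,0,0.14,0,0.08,0.20,0.26,0.30,0,0
22,78,0,0.17,0.16,0.17,0.19,0.17,0.21,0,0.06,0.09,0,0,0.13,0
47,94,0,0,0.27,0.17,0.33,0.16,0.11,0.23,0,0.20,0.27,0,0.15,0
30,31,0,0.22,0.16,0.13,0.19,0,0.11,0.17,0,0,0,0.27,0.17,0
28,75,1,0,0,0.16,0.22,0.23,0.09,0,0,0.13,0.29,0.25,0,0
75,76,0.67,0,0,0,0.16,0.19,0.08,0,0,0.11,0.40,0.31,0,0
48,75,0.70,0,0,0,0.16,0.18,0,0,0,0.11,0.34,0.27,0.17,0
77,78,0,0.19,0,0,0.24,0,0.18,0,0,0.16,0.32,0.30,0.13,0
30,78,0,0.17,0.16,0,0.18,0,0.09,0,0,0.10,0,0,0.14,0
31,69,0,0.16,0.28,0.14,0,0.16,0,0,0,0,0,0.30,0,0.22
1,28,0,0,0,0,0.20,0.18,0,0,0,0.10,0.26,0,0,0.21
22,69,0,0.16,0,0.18,0,0.15,0,0,0.08,0,0,0,0,0.22
28,29,0.53,0,0,0,0,0,0,0,0,0,0.25,0,0,0.13
28,76,0,0,0,0,0,0,0,0,0,0,0.25,0,0,0.12
69,70,0,0,0,0,0,0,0,0,0,0,0,0,0,0.14
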