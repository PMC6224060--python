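node_i,node_j,M1,M2,M3,M4,M5,M6,M7,M8,M9,M10,M11,M12,M13,M14
31,78,0.41,0.58,0.73,0.47,0.50,0.6,0.79,0.73,0.62,1.00,0.68,0.67,0.90,0.90
29,76,0.40,0,0.64,0.43,0.30,0.52,0.68,0.19,0.50,0.80,0.26,0.43,0.52,0.61
30,77,0.29,0.30,0.44,0.34,0,0.37,0.47,0.39,0.40,0.74,0.29,0.40,0.41,0.76
22,31,0.26,0.35,0,0,0.34,0.24,0.40,0.32,0.28,0.35,0.42,0.44,0.53,0.59
69,78,0.29,0.32,0.41,0.28,0,0.32,0.53,0.40,0.20,0.69,0.43,0.41,0.57,0
28,75,0.53,0,0.50,0.37,0.23,0.34,0.45,0,0,0.61,0.19,0.29,0.43,0.38
54,64,0.28,0.25,0.58,0.30,0.29,0.47,0.52,0,0.40,0.45,0.40,0,0.34,0
1,48,0.42,0,0.43,0.44,0.22,0.31,0.43,0.08,0,0,0.21,0,0.43,0.50
36,83,0,0.23,0,0.33,0.44,0.46,0.59,0.34,0,0.50,0,0,0.38,0
47,94,0,0,0,0.34,0.30,0.47,0,0.43,0.32,0.36,0,0.38,0,0.52
75,76,0.26,0,0.46,0.29,0,0.35,0,0,0.18,0.56,0,0.31,0,0
77,78,0,0.24,0,0,0,0.37,0.43,0.19,0,0.34,0.23,0,0,0.62
30,31,0,0.25,0,0.27,0,0.30,0,0.17,0,0,0.20,0.30,0,0.46
48,75,0.34,0,0,0.34,0,0.28,0,0,0,0.50,0,0.29,0.39,0.39
22,69,0,0,0,0,0.21,0.27,0,0.13,0,0,0.21,0.41,0.40,0
24,36,0,0,0,0,0,0.29,0.39,0.15,0.30,0.43,0,0,0,0
22,78,0,0.17,0,0,0,0,0,0.24,0,0,0.22,0,0.39,0.34
31,69,0,0.23,0,0,0,0,0.44,0,0,0,0.36,0.37,0,0
31,77,0,0.25,0,0,0,0.30,0,0,0,0,0.22,0,0,0.49
28,29,0.29,0,0,0,0,0,0,0,0.19,0.50,0,0,0.40,0
23,47,0,0.16,0,0,0,0,0,0,0,0,0,0.29,0.38,0
1,28,0.27,0,0,0.28,0,0,0,0,0,0,0,0,0,0.36
29,75,0.28,0,0,0,0,0,0,0,0,0.47,0,0.27,0,0
21,22,0,0.22,0,0,0,0,0,0,0,0,0,0,0.36,0
28,48,0.27,0,0,0,0,0,0,0,0,0,0,0,0,0.35
30,78,0,0,0,0,0,0,0,0.12,0,0,0,0,0,0.51
22,77,0,0,0,0,0,0,0,0,0,0,0.19,0,0,0
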