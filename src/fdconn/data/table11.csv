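group,node_i,node_j,p_value,adjusted_p_value
46-50,24,36,0.001,0.03
46-50,30,77,0.008,0.232
46-50,69,78,0.009,0.252
46-50,31,78,0.012,0.324
46-50,28,29,0.012,0.324
46-50,29,76,0.013,0.325
46-50,30,31,0.024,0.576
46-50,28,76,0.026,0.598
46-50,75,76,0.031,0.682
46-50,31,77,0.036,0.756
46-50,28,75,0.078,1
46-50,29,75,0.08,1
46-50,77,78,0.083,1
46-50,31,69,0.084,1
46-50,48,75,0.097,1
46-50,22,69,0.124,1
46-50,47,94,0.133,1
46-50,36,83,0.191,1
46-50,30,78,0.204,1
46-50,22,31,0.237,1
46-50,22,78,0.355,1
46-50,69,70,0.486,1
46-50,22,77,0.566,1
46-50,1,48,0.601,1
46-50,23,47,0.601,1
46-50,1,28,0.635,1
46-50,28,48,0.714,1
46-50,21,22,0.929,1
46-50,54,64,1,1
71-79,31,78,0.001,0.03
71-79,22,31,0.003,0.087
71-79,28,75,0.006,0.168
71-79,22,78,0.01,0.27
71-79,28,29,0.014,0.364
71-79,30,77,0.018,0.45
71-79,30,78,0.018,0.45
71-79,75,76,0.028,0.644
71-79,29,76,0.03,0.66
71-79,69,78,0.031,0.66
71-79,77,78,0.031,0.66
71-79,48,75,0.039,0.741
71-79,28,48,0.041,0.741
71-79,21,22,0.046,0.782
71-79,47,94,0.067,1
71-79,24,36,0.082,1
71-79,30,31,0.088,1
71-79,22,69,0.09,1
71-79,31,77,0.091,1
71-79,1,48,0.102,1
71-79,28,76,0.103,1
71-79,1,28,0.167,1
71-79,23,47,0.205,1
71-79,36,83,0.305,1
71-79,69,70,0.728,1
71-79,29,75,0.776,1
71-79,31,69,0.803,1
71-79,54,64,1,1
71-79,22,77,1,1
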