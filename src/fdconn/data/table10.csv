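group,p_value,adjusted_p_value,significant_links
6-15,0.763,1.000,
16-21,0.026,0.130,
26-35,0.823,1.000,
36-40,0.071,0.284,
46-50,0.007,0.042,24-36
58-70,0.696,1.000,
71-79,0.005,0.035,31-78;(22-31)
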