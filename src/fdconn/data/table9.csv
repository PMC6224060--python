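label,merged_id,source_group_ids,age_lo,age_hi,n_male,n_female
6-15,1,1;2,6,15,10,9
16-21,2,3;4,16,25,7,18
26-35,3,5;6,26,35,9,11
36-40,4,7;8,36,45,7,9
46-50,5,9;10,46,57,6,13
58-70,6,11;12,58,70,5,10
71-79,7,13;14,71,79,7,12
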