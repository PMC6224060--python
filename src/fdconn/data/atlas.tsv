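node_id	hemisphere	region_name
1	left	Left Frontal Pole
2	left	Left Insular Cortex
3	left	Left Superior Frontal Gyrus
4	left	Left Middle Frontal Gyrus
5	left	Left Inferior Frontal Gyrus, pars triangularis
6	left	Left Inferior Frontal Gyrus, pars opercularis
7	left	Left Precentral Gyrus
8	left	Left Temporal Pole
9	left	Left Superior Temporal Gyrus, anterior division
10	left	Left Superior Temporal Gyrus, posterior division
11	left	Left Middle Temporal Gyrus, anterior division
12	left	Left Middle Temporal Gyrus, posterior division
13	left	Left Middle Temporal Gyrus, temporooccipital part
14	left	Left Inferior Temporal Gyrus, anterior division
15	left	Left Inferior Temporal Gyrus, posterior division
16	left	Left Inferior Temporal Gyrus, temporooccipital part
17	left	Left Postcentral Gyrus
18	left	Left Superior Parietal Lobule
19	left	Left Supramarginal Gyrus, anterior division
20	left	Left Supramarginal Gyrus, posterior division
21	left	Left Angular Gyrus
22	left	Left Lateral Occipital Cortex, superior division
23	left	Left Lateral Occipital Cortex, inferior division
24	left	Left Intracalcarine Cortex
25	left	Left Frontal Medial Cortex
26	left	Left Juxtapositional Lobule Cortex (formerly Supplementary Motor Cortex)
27	left	Left Subcallosal Cortex
28	left	Left Paracingulate Gyrus
29	left	Left Cingulate Gyrus, anterior division
30	left	Left Cingulate Gyrus, posterior division
31	left	Left Precuneus Cortex
32	left	Left Cuneal Cortex
33	left	Left Frontal Orbital Cortex
34	left	Left Parahippocampal Gyrus, anterior division
35	left	Left Parahippocampal Gyrus, posterior division
36	left	Left Lingual Gyrus
37	left	Left Temporal Fusiform Cortex, anterior division
38	left	Left Temporal Fusiform Cortex, posterior division
39	left	Left Temporal Occipital Fusiform Cortex
40	left	Left Occipital Fusiform Gyrus
41	left	Left Frontal Operculum Cortex
42	left	Left Central Opercular Cortex
43	left	Left Parietal Operculum Cortex
44	left	Left Planum Polare
45	left	Left Heschl's Gyrus (includes H1 and H2)
46	left	Left Planum Temporale
47	left	Left Occipital Pole
48	right	Right Frontal Pole
49	right	Right Insular Cortex
50	right	Right Superior Frontal Gyrus
51	right	Right Middle Frontal Gyrus
52	right	Right Inferior Frontal Gyrus, pars triangularis
53	right	Right Inferior Frontal Gyrus, pars opercularis
54	right	Right Precentral Gyrus
55	right	Right Temporal Pole
56	right	Right Superior Temporal Gyrus, anterior division
57	right	Right Superior Temporal Gyrus, posterior division
58	right	Right Middle Temporal Gyrus, anterior division
59	right	Right Middle Temporal Gyrus, posterior division
60	right	Right Middle Temporal Gyrus, temporooccipital part
61	right	Right Inferior Temporal Gyrus, anterior division
62	right	Right Inferior Temporal Gyrus, posterior division
63	right	Right Inferior Temporal Gyrus, temporooccipital part
64	right	Right Postcentral Gyrus
65	right	Right Superior Parietal Lobule
66	right	Right Supramarginal Gyrus, anterior division
67	right	Right Supramarginal Gyrus, posterior division
68	right	Right Angular Gyrus
69	right	Right Lateral Occipital Cortex, superior division
70	right	Right Lateral Occipital Cortex, inferior division
71	right	Right Intracalcarine Cortex
72	right	Right Frontal Medial Cortex
73	right	Right Juxtapositional Lobule Cortex (formerly Supplementary Motor Cortex)
74	right	Right Subcallosal Cortex
75	right	Right Paracingulate Gyrus
76	right	Right Cingulate Gyrus, anterior division
77	right	Right Cingulate Gyrus, posterior division
78	right	Right Precuneus Cortex
79	right	Right Cuneal Cortex
80	right	Right Frontal Orbital Cortex
81	right	Right Parahippocampal Gyrus, anterior division
82	right	Right Parahippocampal Gyrus, posterior division
83	right	Right Lingual Gyrus
84	right	Right Temporal Fusiform Cortex, anterior division
85	right	Right Temporal Fusiform Cortex, posterior division
86	right	Right Temporal Occipital Fusiform Cortex
87	right	Right Occipital Fusiform Gyrus
88	right	Right Frontal Operculum Cortex
89	right	Right Central Opercular Cortex
90	right	Right Parietal Operculum Cortex
91	right	Right Planum Polare
92	right	Right Heschl's Gyrus (includes H1 and H2)
93	right	Right Planum Temporale
94	right	Right Occipital Pole
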