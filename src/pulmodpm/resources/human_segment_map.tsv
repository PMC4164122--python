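feeding_airway_id	segment_id	side
10	19	right
10	20	right
17	21	right
16	22	right
16	23	right
11	24	right
11	25	right
11	26	right
12	29	right
12	34	right
13	27	left
13	28	left
13	30	left
14	31	left
14	32	left
15	33	left
15	35	left
18	36	left
18	37	left
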