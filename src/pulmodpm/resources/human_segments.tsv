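id	volume_pct	height_pct
19	6.4	76.1
20	5.5	69
21	6.7	89
22	3.4	39
23	4	22.3
24	5.8	35.9
25	4.3	0
26	5.1	2.3
27	5.3	9.8
28	4.8	16.1
29	7.3	14
30	6.2	6.4
31	8.4	6.2
32	7.4	41.3
33	4.2	78.2
34	4	1
35	4	94
36	4.1	51.9
37	3.1	40.6
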