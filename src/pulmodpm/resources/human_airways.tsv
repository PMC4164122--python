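id	length_mm	diameter_mm
1	100	16
2	22	11.1
3	50	12
4	15.6	7.3
5	26	8.9
6	11	8
7	16	7.5
8	6.4	8.5
9	8	6.4
10	21	5.2
11	18	6.5
12	14	7.3
13	8.4	6
14	4.5	7
15	13.5	5.3
16	11	5.5
17	6.2	3.2
18	14.8	6.2
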