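id	length_mm	volume
1	91.1	8.6
2	40	3.8
3	8.2	0.05
4	15	0.29
5	16	0.36
6	8.2	0.05
19	-	12.1%
20	-	31.1%
21	-	4.9%
22	-	9.4%
23	-	13.5%
24	-	29.1%
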