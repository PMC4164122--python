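parent_id	child_id
1	2
1	3
2	4
2	5
5	6
5	7
3	8
3	9
4	10
4	17
6	16
7	11
7	12
8	13
8	14
9	15
9	18
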