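parent_id	child_id
1	2
1	3
2	4
3	5
3	6
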