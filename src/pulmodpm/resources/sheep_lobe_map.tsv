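feeding_airway_id	lobe_id	side	lobe	height_pct
4	19	left	apical	70
4	20	left	diaphragmatic	30
5	21	right	apical	75
5	22	right	middle	45
6	23	right	accessory	20
6	24	right	diaphragmatic	25
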