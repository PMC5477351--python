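id	label
D009069	Movement Disorders
D009336	Necrosis
D023921	Coronary Stenosis
D054059	Coronary Occlusion
D002637	Chest pain
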