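id	label
HP:0005145	Coronary artery stenosis
HP:0100749	Chest pain
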