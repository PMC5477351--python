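id	label
233970002	Coronary artery stenosis
2929001	Occlusion of artery
63739005	Coronary occlusion
29857009	Chest pain
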