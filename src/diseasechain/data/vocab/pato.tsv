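id	label
PATO:0002037	degeneration
PATO:0000386	hard
PATO:0000586	increased size
PATO:0001625	increased functionality
PATO:0000647	necrotic
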