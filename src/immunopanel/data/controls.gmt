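control	15 randomly chosen non-immune control genes	AMIGO1	CDH1	CYCS	EFNA3	EFNA5	EPHA7	NFKBIE	NKIRAS1	P4HA2	S100A5	S1PR2	SDHA	SEMA3F	SEMA4B	SEMA5A
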