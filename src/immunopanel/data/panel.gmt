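activation	immune activation genes	IFNG	CXCL9	CXCL10	CD8A	PRF1	GZMB
checkpoint	immune checkpoint pathway genes	PDCD1	CD274	PDCD1LG2	CTLA4	CD80	CD86	LAG3	HAVCR2	BTLA
immunogenicity	union of activation and checkpoint genes	IFNG	CXCL9	CXCL10	CD8A	PRF1	GZMB	PDCD1	CD274	PDCD1LG2	CTLA4	CD80	CD86	LAG3	HAVCR2	BTLA
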