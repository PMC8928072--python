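alias	symbol
PD-1	PDCD1
PD1	PDCD1
PD-L1	CD274
PDL1	CD274
PD-L2	PDCD1LG2
PDL2	PDCD1LG2
CTLA-4	CTLA4
LAG-3	LAG3
TIM-3	HAVCR2
TIM3	HAVCR2
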