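M1	classically_activated_macrophage_program	CXCL9	CXCL10	IL1B	TNF	CD80	CD86	NOS2	IL6
M2	alternatively_activated_macrophage_program	MRC1	CD163	MSR1	CCL22	IL10	TGFB1
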