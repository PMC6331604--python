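POS_AP	na	ANXA2	CD44	DPEP1	IGBP2	IQGAP2	MMP2	MTTP	NCF1C	STEAP3	TCF19	TEAD	TM6SF2
NEG_AP	na	ALOXE3	GABRD	LOC293392	LOC440905	PANX2	SGSM1
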