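naive	T-cell naive markers (convenience panel)	SELL	CCR7	LEF1	TCF7
resident	T-cell tissue-residency markers (convenience panel)	CD69	RUNX3	NR4A1	ITGAE	RGS1
exhausted	T-cell exhaustion markers (convenience panel)	CTLA4	TIGIT	PDCD1	LAG3	HAVCR2	TNFRSF9
cytotoxic	Cytotoxicity markers (convenience panel)	NKG7	GNLY	GZMB	GZMH	GZMK	IFNG	PRF1
costimulatory	Co-stimulatory markers (convenience panel)	ICOS	CD28	TNFRSF4	TNFRSF14	CD27
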