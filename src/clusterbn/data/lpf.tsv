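symptom	ATS	BDL	NAR	HST	PAG	norm	pd
LPF-Identity	69.3	87.9	65.7	77.9	67.1	15.0	57.9
LPF-Self-direction	62.1	80.0	51.4	65.0	70.0	22.1	49.3
LPF-Empathy	85.0	75.7	65.0	70.0	78.6	15.0	27.1
LPF-Intimacy	80.0	79.3	43.6	75.7	69.3	12.9	45.7
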