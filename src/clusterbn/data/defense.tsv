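symptom	ATS	BDL	NAR	HST	PAG	norm	pd
MD-Acting-out	85.7	84.3	—	70.0	—	27.9	60.0
MD-Idealization	—	67.1	—	—	—	27.1	44.3
MD-Denial	75.7	78.6	80.0	77.1	—	38.6	28.6
MD-Dissociation	47.1	—	55.0	72.1	—	15.0	55.0
MD-Devaluation	—	85.0	44.3	—	—	17.9	69.3
MD-Projection	76.4	—	70.0	—	—	42.1	34.3
MD-Projective-identification	—	—	—	—	77.9	21.4	62.9
MD-Splitting	—	87.9	—	72.1	—	22.9	64.3
MD-Displacement	—	—	—	—	70.0	24.3	54.3
MD-Passive-aggression	—	71.4	—	58.6	88.6	24.3	48.6
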