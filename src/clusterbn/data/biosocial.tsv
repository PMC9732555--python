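symptom	ATS	BDL	NAR	HST	PAG	norm_high	norm_low	pd
BIO-Pleasure	—	-72.9	+77.1	+58.6	-57.1	40.0	22.5	N/A
BIO-Pain	—	+67.9	—	-44.3	+72.1	30.0	20.0	N/A
BIO-Active	—	—	+74.3	+55.0	—	47.5	—	N/A
BIO-Passive	—	+56.4	—	-63.6	+59.3	25.0	22.5	N/A
BIO-Self	+82.1	—	+85.7	-41.4	—	30.0	15.0	N/A
BIO-Other	—	—	—	+20.7	—	20.0	—	N/A
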