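disorder	clinical	general	pd
ATS	12.4	2.4	70.0
BDL	19.3	3.5	87.1
NAR	11.9	4.3	61.4
HST	13.3	3.6	72.9
PAG	9.1	3.0	62.1
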