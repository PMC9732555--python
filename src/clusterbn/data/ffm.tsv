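symptom	ATS	BDL	NAR	HST	PAG	norm	pd
FFM-Anxiety	-57.9	+77.9	—	—	—	44.3	70.7
FFM-Angry-hostility	+77.1	+80.7	+62.9	—	+77.1	35.7	52.1
FFM-Depression	—	+77.1	—	+47.9	—	46.4	77.9
FFM-Self-consciousness	-67.9	—	—	—	—	34.3	71.4
FFM-Impulsiveness	+83.6	+83.6	—	—	—	37.1	55.7
FFM-Vulnerability	—	+80.0	—	+68.6	—	32.9	75.0
FFM-Warmth	-63.6	-48.6	-63.6	—	—	32.9	34.3
FFM-Gregariousness	-54.3	-38.6	—	+75.0	—	24.3	38.6
FFM-Assertiveness	—	—	+62.9	—	-77.1	33.6	61.4
FFM-Activity	—	—	—	+57.9	—	47.9	25.7
FFM-Excitement-seeking	+65.0	—	+49.3	+65.7	—	41.4	30.0
FFM-Positive-emotions	—	—	—	+54.3	—	27.9	70.7
FFM-Fantasy	—	+60.0	+79.3	+77.9	—	35.0	N/A
FFM-Feelings	—	—	—	+57.9	—	25.7	N/A
FFM-Actions	—	+43.6	—	+65.7	—	33.6	N/A
FFM-Trust	-75.0	-65.0	-56.4	+59.3	-73.6	38.6	45.7
FFM-Straightforwardness	-84.3	-62.1	-73.6	—	-75.0	35.7	24.3
FFM-Altruism	-86.4	—	-76.4	—	—	33.6	18.6
FFM-Compliance	-86.4	-70.0	-75.7	—	-75.7	27.1	46.4
FFM-Modesty	-65.0	—	-87.1	—	—	38.6	24.3
FFM-Tender-mindedness	-80.7	—	-75.0	—	—	24.3	17.1
FFM-Competence	—	-75.7	+76.4	—	-70.7	25.0	69.3
FFM-Order	—	-54.3	—	—	—	36.4	36.4
FFM-Dutifulness	-80.7	—	—	—	-70.0	32.1	28.6
FFM-Self-discipline	-68.6	—	—	—	-64.3	40.0	45.7
FFM-Deliberation	-74.3	-82.1	—	-70.0	—	32.9	45.7
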