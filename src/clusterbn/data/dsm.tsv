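symptom	ATS	BDL	NAR	HST	PAG	norm	pd
DSM-ATS-01	76.4	—	—	—	—	11.4	46.4
DSM-ATS-02	81.4	—	—	—	—	27.9	28.6
DSM-ATS-03	64.3	75.0	—	—	—	36.4	52.1
DSM-ATS-04	77.1	70.7	—	—	—	35.0	60.7
DSM-ATS-05	65.7	66.4	—	—	—	25.7	41.4
DSM-ATS-06	81.4	—	—	—	—	22.9	36.4
DSM-ATS-07	80.7	—	73.6	—	—	11.4	27.1
DSM-BDL-01	—	81.4	—	64.3	—	26.4	69.3
DSM-BDL-02	—	86.4	—	65.0	—	17.9	67.1
DSM-BDL-03	—	88.6	—	—	—	11.4	76.4
DSM-BDL-04	—	85.7	—	—	—	17.1	78.6
DSM-BDL-05	—	76.4	—	—	—	15.7	78.6
DSM-BDL-06	—	85.7	—	72.1	—	17.9	79.3
DSM-BDL-07	—	82.1	—	—	—	16.4	79.3
DSM-BDL-08	75.7	80.7	—	—	—	22.9	72.9
DSM-BDL-09	—	63.6	—	40.7	—	10.0	75.7
DSM-NAR-01	—	—	85.7	—	—	23.6	14.3
DSM-NAR-02	—	—	85.7	—	—	22.9	16.4
DSM-NAR-03	—	—	91.4	—	—	25.0	19.3
DSM-NAR-04	—	—	90.0	80.0	—	22.1	26.4
DSM-NAR-05	—	—	84.3	—	—	23.6	14.3
DSM-NAR-06	—	—	85.7	—	—	29.3	25.0
DSM-NAR-07	79.3	—	77.1	—	—	16.4	22.1
DSM-NAR-08	—	—	77.1	—	77.9	32.1	23.6
DSM-NAR-09	—	—	86.4	—	—	24.3	19.3
DSM-HST-01	—	—	—	87.9	—	16.4	48.6
DSM-HST-02	—	—	—	81.4	—	19.3	45.0
DSM-HST-03	—	—	—	78.6	—	21.4	55.7
DSM-HST-04	—	—	—	81.4	—	22.1	35.0
DSM-HST-05	—	—	—	77.9	—	22.1	27.1
DSM-HST-06	—	—	—	87.9	—	15.7	42.1
DSM-HST-07	—	63.6	—	82.1	—	25.0	35.7
DSM-HST-08	—	62.1	—	80.7	—	17.1	44.3
DSM-PAG-01	67.1	—	—	—	82.9	22.1	57.1
DSM-PAG-02	—	—	—	61.4	77.9	17.1	57.9
DSM-PAG-03	72.9	—	—	—	77.1	22.1	67.9
DSM-PAG-04	75.0	—	—	—	76.4	22.9	57.9
DSM-PAG-05	—	—	65.0	—	74.3	22.9	52.9
DSM-PAG-06	—	—	—	—	76.4	24.3	57.9
DSM-PAG-07	—	—	—	—	86.4	19.3	64.3
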