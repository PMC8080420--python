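no	source	target	sim_dld	sim_ld	sim_ndist	sim_soft_half	sim_soft_applied	anomalous
1	precede	preceed	0.86	0.71	0.79	1.00	0.97	0
2	promise	promiss	0.86	0.86	0.93	1.00	0.97	0
3	absence	absense	0.86	0.86	0.86	0.86	0.94	0
4	achieve	acheive	0.86	0.71	0.71	0.86	0.94	0
5	accidentally	accidentaly	0.92	0.92	0.92	0.96	0.96	0
6	algorithm	algorythm	0.89	0.89	0.89	0.89	0.96	0
7	similar	Similer	0.86	0.86	0.86	0.86	0.94	0
8	dilemma	Dilemma	0.86	0.86	0.86	0.93	0.93	1
9	almost	allmost	0.86	0.86	0.86	0.93	0.93	0
10	amend	ammend	0.83	0.83	0.83	0.92	0.92	0
11	occurred	occured	0.88	0.88	0.88	0.94	0.94	0
12	embarrass	embarass	0.89	0.89	0.89	1.00	0.94	0
13	harass	harrass	0.86	0.86	0.86	1.00	0.93	0
14	really	Realy	0.83	0.83	0.83	0.92	0.92	0
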