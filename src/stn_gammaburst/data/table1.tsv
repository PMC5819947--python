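case	age	gender	center	disease_duration_y	predominant_symptoms	updrs_med_on	updrs_med_off	delta_updrs_stim_pct	medication_decrease_pct
1	59	M	Berlin	10	Bradykinesia, Rigidity	NA	26	42	NA
2	44	M	Berlin	12	Bradykinesia, Rigidity, Resting Tremor	31	41	25	NA
3	42	M	Berlin	4	Action Tremor, Resting Tremor, Gait Disturbance	16	42	60	100
4	53	M	Berlin	8	Bradykinesia, Rigidity, Resting Tremor	3	20	53	68
5	70	M	Berlin	19	Bradykinesia, Rigidity, Resting Tremor	38	48	NA	NA
6	55	M	Berlin	15	Peak-Dose Dyskinesia, Wearing-Off	18	32	75	50
7	71	F	Berlin	18	Bradykinesia	17	34	39	45.5
8	68	M	Berlin	20	Speech Difficulties, Hypokinesia	16	20	40	61.3
9	67	M	Berlin	14	Bradykinesia	14	24	74	50
10	49	M	Hannover	7	Rigidity	19	40	50	14.3
11	39	F	Berlin	6	Resting Tremor, Action Tremor	21	NA	NA	68.4
12	71	M	Berlin	4	Resting Tremor	20	23	NA	55.2
13	68	F	Berlin	5	Resting Tremor	14	20	NA	74.3
14	58	M	Berlin	12	Bradykinesia, Fluctuations, Freezing	NA	35	69	36.3
15	75	M	Berlin	15	Action Tremor, Resting Tremor	20	38	69	50
16	53	M	Hannover	10	Bradykinesia, Rigidity	24	42	53	33.3
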