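subject	group	sex	age	education	grade	location	resection	aq_pre	aq_w2	aq_m1	aq_m3	aq_m6
P009	good	M	30	12	2	Ins	PR	84.91		79.91	79.18	84.05
P011	good	M	23	9	2	F	GTR	90.88		72.09		91.33
P016	good	M	36	12	2	F	STR	95.78	87.48			93.04
P017	good	M	38	14	3	F	GTR	97.2	42.74		85.1
P018	good	F	67	3	3	T	GTR	82.16	51.26			70.81
P030	good	M	46	6	4	F	GTR	82.07		65.83	73.71
P043	good	M	43	18	2	F	GTR	90.4	68.55		91.82
P046	good	F	32	9	2	F	GTR	95.1		88.42	92.7
P049	good	M	29	16	3	F	GTR	97.2		85.9	97.77
P051	good	M	52	16	4	T	GTR	80.52	59.28		79.82
P053	good	F	29	14	2	T	GTR	100	81.58		100
P071	good	M	41	16	2	Ins	STR	96.85		84.63	95.2
P072	good	M	59	1	2	T	PR	68.54	39.02		56.6
P075	good	M	36	19	2	Ins	PR	98.77	14.83		98.03
P081	good	M	61	6	4	F	PR	87.95	55.25		87.36
P094	good	M	50	16	3	T	GTR	98.2	67.37		92.21
P096	good	F	39	9	2	P	STR	87.93	24.95		77.79
P100	good	M	33	21	2	T	GTR	97.2	81.9		97.8
P103	good	F	39	4	3	F	GTR	84.36		41.61	71.46
P105	good	M	28	12	2	F	GTR	97.1	64.57		94.42
P201	good	M	55	12	2	Ins	PR	94.81		84.51	90.13
P204	good	F	59	12	4	P	GTR	91.82		87.14	86.17
P210	good	F	40	9	2	T	GTR	95.4		87.5	87.08
P217	good	F	31	16	2	T	GTR	96.53	79.62	97.76	99.45
P218	good	M	28	19	4	F	GTR	93.06	62.77	84.31	92.52
P219	good	M	42	16	2	Ins	PR	99.05	14.37	91.96	96.29
P220	good	M	50	9	2	F	PR	95.97		75.27	89.42
P221	good	M	62	12	2	F	GTR	79.89	23.39	81.07	84.25
P028	poor	F	36	16	2	P	GTR	97.42		63.52		70.58
P044	poor	M	49	12	2	P	GTR	95.4	49.85		80.98
P047	poor	F	60	0	3	T	STR	66.89		50.23	52.39
P048	poor	F	63	14	3	F	GTR	70.37		45.87		51.17
P101	poor	M	42	19	4	P	GTR	90.67		65.07	72.25
P106	poor	M	56	6	4	T	GTR	84.43	64.9		69.98
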