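table	variable	unit	timepoint	obs_mean	obs_sd	ctrl_mean	ctrl_sd	n	t	p
I	CK-MB	U/L	before	35.12	5.36	34.98	5.17	36	0.113	>0.05
I	CK-MB	U/L	after	9.43	2.25	16.07	2.87	36	10.924	<0.05
I	cTnI	ng/ml	before	0.14	0.08	0.15	0.11	36	0.441	>0.05
I	cTnI	ng/ml	after	0.25	0.12	0.43	0.13	36	6.105	<0.05
I	Myo	ug/L	before	158.74	44.72	156.83	43.57	36	0.184	>0.05
I	Myo	ug/L	after	34.25	11.02	40.36	11.78	36	2.273	<0.05
I	LVEF	%	before	42.76	5.08	43.15	4.86	36	0.333	>0.05
I	LVEF	%	after	60.32	4.56	52.53	4.86	36	7.013	<0.05
II	hsCRP	mg/L	before	3.76	1.05	3.98	1.37	36	0.765	>0.05
II	hsCRP	mg/L	after	2.13	0.86	3.25	0.89	36	5.429	<0.05
II	VEGF	ng/L	before	60.49	10.56	59.87	10.23	36	0.253	>0.05
II	VEGF	ng/L	after	75.18	10.87	68.75	10.46	36	2.557	<0.05
II	ET-1	umol/L	before	85.58	19.25	86.93	18.78	36	0.301	>0.05
II	ET-1	umol/L	after	42.36	16.49	58.42	15.93	36	4.203	<0.05
III	NO	umol/L	before	63.47	10.86	62.98	12.52	36	0.177	>0.05
III	NO	umol/L	after	52.13	8.89	57.46	9.25	36	2.493	<0.05
III	NOS	U/L	before	0.032	0.007	0.031	0.008	36	0.564	>0.05
III	NOS	U/L	after	0.017	0.006	0.022	0.005	36	3.841	<0.05
III	iNOS	U/L	before	0.020	0.006	0.019	0.005	36	0.768	>0.05
III	iNOS	U/L	after	0.012	0.005	0.017	0.004	36	4.685	<0.05
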