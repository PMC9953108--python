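genome_id	orphan	pair	triad	tetrad	pentad	total_tcs
Leptodesmis_A121	92	12	5	0	0	131
Leptolyngbya_JSC-1	137	35	9	0	1	239
Leptothermofonsia_E412	120	17	4	1	1	175
Thermoleptolyngbya_A183	91	8	1	0	1	115
Thermoleptolyngbya_O-77	84	14	1	0	1	120
Thermostichus_60AY4M2	46	1	1	0	0	51
Thermostichus_63AY4M2	46	1	1	0	0	51
Thermostichus_65AY6A5	46	1	1	0	0	51
Thermostichus_65AY6Li	44	2	1	0	0	51
Thermostichus_JA-2-3Ba	39	3	2	0	0	51
Thermostichus_JA-3-3Ab	42	3	1	0	0	51
Thermosynechococcus_PCC6715	42	2	1	0	0	49
Thermosynechococcus_CL-1	33	7	0	0	0	47
Thermosynechococcus_TA-1	35	6	0	0	0	47
Thermosynechococcus_BP-1	32	5	0	0	0	42
Thermosynechococcus_E542	38	3	0	0	0	44
Thermosynechococcus_NIES-2134	36	3	0	0	0	42
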