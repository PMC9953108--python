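genome_id	genome_size_mb	n_cds	cHK	hyHK	uHK	CheA	RR	PP-HisKA	PP-Hpt
Leptodesmis_A121	5.35	4917	42	23	1	2	61	1	1
Leptolyngbya_JSC-1	7.87	7423	69	49	1	6	111	3	0
Leptothermofonsia_E412	6.43	5495	60	30	2	3	79	0	1
Thermoleptolyngbya_A183	5.53	4541	51	15	1	2	46	0	0
Thermoleptolyngbya_O-77	5.48	4865	53	14	0	2	49	2	0
Thermostichus_60AY4M2	3.16	2622	16	1	1	2	29	2	0
Thermostichus_63AY4M2	3.09	2577	15	0	2	2	30	2	0
Thermostichus_65AY6A5	2.98	2597	17	1	1	2	28	2	0
Thermostichus_65AY6Li	2.93	2632	15	1	2	2	29	2	0
Thermostichus_JA-2-3Ba	3.05	2862	16	1	2	2	28	2	0
Thermostichus_JA-3-3Ab	2.93	2760	15	1	2	2	29	2	0
Thermosynechococcus_PCC6715	2.66	2465	8	3	0	2	32	2	2
Thermosynechococcus_CL-1	2.65	2549	13	4	0	2	26	1	1
Thermosynechococcus_TA-1	2.66	2556	12	4	0	2	26	1	2
Thermosynechococcus_BP-1	2.59	2475	10	4	0	3	23	1	1
Thermosynechococcus_E542	2.65	2543	10	3	0	3	26	1	1
Thermosynechococcus_NIES-2134	2.57	2496	10	4	0	2	24	1	1
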