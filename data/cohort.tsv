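individual_id	family_id	sex	age	taad	arterial_other	cardio_other	connective	reported_z
II:8	FAM1	male	64	0	0	1	1	
II:4	FAM1	male	77	0	0	1	1	
III:5	FAM1	male	49	0	0	1	1	
III:9	FAM1	male	36	0	0	0	1	2.0
II:10	FAM1	male		0	1	1	1	
III:2	FAM1	female		0	0	1	1	
III:7	FAM1	male		0	0	1	1	
III:11	FAM1	male	7	0	0	0	0	
IV:1	FAM1	male		0	0	0	1	
III:13	FAM1	female		0	0	0	1	
II:8	FAM2	male	74	1	0	1	1	5.2
II:2	FAM2	male	80	1	0	1	1	2.1
II:5	FAM2	female	55	0	0	1	0	
III:4	FAM2	female	44	0	0	0	0	
III:5	FAM2	female	41	0	0	0	0	1.7
III:7	FAM2	male		0	0	0	0	
II:1	FAM3	male	15	0	0	0	1	0.0
III:6	FAM4	male	31	1	0	0	0	
II:2	FAM4	male	76	0	0	0	0	
II:4	FAM4	female		0	0	0	0	
III:2	FAM4	female		0	0	0	0	
III:8	FAM4	female		0	0	0	0	
IV:1	FAM4	male	5	0	0	0	0	
IV:2	FAM4	female		0	0	0	0	
III:2	FAM5	female	50	0	0	0	1	
II:1	FAM5	male	75	1	0	0	1	6.4
IV:1	FAM5	male	25	0	0	0	0	
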