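FAM1	P1	1	150	152	152	154	174	176	156	158	158	160	160	162	182	184	184	186	186	188	188	190	190	192
FAM2	P2	1	150	150	152	152	178	180	156	156	158	158	160	160	186	188	188	190	190	192	192	194	194	196
FAM3	P3	1	148	150	150	152	174	178	154	156	156	158	158	160	182	186	184	188	186	190	188	192	190	194
FAM4	P4	1	150	154	152	156	176	180	156	160	158	162	160	164	184	188	186	190	188	192	190	194	192	196
FAM5	P5	1	150	152	152	154	174	176	156	158	158	160	160	162	182	184	184	186	186	188	188	190	190	192
FAM1	P6	1	146	150	148	152	178	180	152	156	154	158	156	160	186	188	188	190	190	192	192	194	194	196
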