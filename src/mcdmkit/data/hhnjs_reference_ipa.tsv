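criterion	importance	performance	quadrant
C11	0.0209	3.8065	II
C12	0.0256	3.8387	II
C13	0.0313	4.1290	I
C14	0.0461	4.3548	I
C15	0.0493	4.3871	I
C21	0.0137	4.1290	II
C22	0.0295	4.1935	II
C23	0.0475	4.0968	I
C24	0.0554	4.4839	I
C31	0.0263	4.0645	II
C32	0.0469	3.6452	IV
C33	0.0551	3.6129	IV
C41	0.0159	3.7419	III
C42	0.0432	3.7742	I
C43	0.0439	3.4194	IV
C44	0.0433	3.4194	IV
C51	0.0432	4.1290	I
C52	0.0662	4.0323	I
C61	0.0170	3.5484	III
C62	0.0312	3.1613	IV
C63	0.0443	3.5484	IV
C71	0.0147	3.9032	II
C72	0.0161	3.3871	III
C73	0.0348	3.6452	IV
C74	0.0317	3.7097	IV
C81	0.0134	3.4516	III
C82	0.0220	3.7097	III
C83	0.0224	3.3226	III
C84	0.0247	3.1290	III
C85	0.0244	3.2903	III
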