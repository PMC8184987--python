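SNP	GENE	CHR	BP	A1	A2	FRQ_A1	OR_DISC	L_DISC	U_DISC	OR_FU	L_FU	U_FU	GROUP
rs876461	PRKD3/NDUFAF7	2	37515958	A	G	0.143	1.07	1.04	1.09	1.08	1.04	1.13	novel
rs34674752	SHARPIN	8	145154222	A	G	0.052	1.11	1.06	1.16	1.20	1.10	1.31	novel
rs34173062	SHARPIN	8	145158607	A	G	0.085	1.16	1.11	1.21	1.09	1.02	1.17	novel
rs3935877	PLCG2	16	81900853	C	T	0.868	0.92	0.90	0.95	0.92	0.85	0.99	novel
rs72835061	CHRNE	17	4805437	A	C	0.085	1.09	1.06	1.12	1.07	1.02	1.12	novel
rs2154481	APP	21	27473875	C	T	0.483	0.95	0.93	0.96	0.96	0.93	0.99	novel
rs4351014	HS3ST1	4	11027619	C	T	0.684	0.94	0.92	0.96	0.93	0.88	0.98	replicated
rs4985556	IL34	16	70694000	A	C	0.111	1.08	1.05	1.11	1.09	1.03	1.16	replicated
rs12444183	PLCG2	16	81773209	A	G	0.407	0.95	0.93	0.97	0.92	0.88	0.96	replicated
rs7153315	ELK2AP	14	106195719	C	G	0.750	0.94	0.92	0.96	1.16	1.01	1.33	suggestive
rs76523702	SPPL2A	15	51002342	C	T	0.802	1.06	1.04	1.08	1.02	0.97	1.07	suggestive
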