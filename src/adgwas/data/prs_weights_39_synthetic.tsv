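SNP	CHR	BP	A1	A2	MAF	WEIGHT	SOURCE
rs_syn001	1	207692049	A	G	0.19	-0.150	synthetic
rs_syn002	1	161155392	T	C	0.42	0.080	synthetic
rs_syn003	2	127892810	G	A	0.39	-0.120	synthetic
rs_syn004	2	234068476	C	T	0.27	0.060	synthetic
rs_syn005	2	37515958	A	G	0.143	0.068	synthetic
rs_syn006	4	11027619	T	C	0.316	0.062	synthetic
rs_syn007	5	86927378	A	G	0.31	-0.050	synthetic
rs_syn008	6	32578530	G	T	0.24	0.110	synthetic
rs_syn009	6	47487762	C	A	0.35	0.070	synthetic
rs_syn010	7	100004446	G	C	0.33	0.090	synthetic
rs_syn011	7	143110762	A	G	0.36	-0.085	synthetic
rs_syn012	8	27467686	T	C	0.38	-0.070	synthetic
rs_syn013	8	145154222	A	G	0.052	0.122	synthetic
rs_syn014	8	145158607	A	G	0.085	0.131	synthetic
rs_syn015	10	11720308	C	T	0.40	0.045	synthetic
rs_syn016	11	59923508	C	T	0.34	0.095	synthetic
rs_syn017	11	85867875	C	T	0.36	-0.110	synthetic
rs_syn018	11	121435587	C	T	0.04	0.180	synthetic
rs_syn019	11	47557871	A	G	0.32	-0.065	synthetic
rs_syn020	14	53400629	T	C	0.45	-0.055	synthetic
rs_syn021	14	92938855	G	A	0.17	0.100	synthetic
rs_syn022	15	59045774	A	G	0.22	0.075	synthetic
rs_syn023	16	81773209	G	A	0.407	0.051	synthetic
rs_syn024	16	70694000	A	C	0.111	0.077	synthetic
rs_syn025	16	81900853	T	C	0.132	0.083	synthetic
rs_syn026	17	4805437	A	C	0.085	0.086	synthetic
rs_syn027	17	56409089	T	C	0.21	-0.090	synthetic
rs_syn028	17	61538148	G	A	0.14	0.120	synthetic
rs_syn029	17	44353222	A	G	0.23	-0.105	synthetic
rs_syn030	18	29088958	T	C	0.12	0.130	synthetic
rs_syn031	19	1063443	G	A	0.32	0.140	synthetic
rs_syn032	19	51727962	T	C	0.30	-0.075	synthetic
rs_syn033	20	54998544	C	T	0.08	0.160	synthetic
rs_syn034	20	55018260	A	G	0.37	-0.060	synthetic
rs_syn035	21	27473875	C	T	0.483	-0.052	synthetic
rs_syn036	21	28156856	A	G	0.29	0.072	synthetic
rs_syn037	22	35879121	G	A	0.16	-0.115	synthetic
rs_syn038	6	41129252	C	G	0.02	0.250	synthetic
rs_syn039	10	82032199	A	G	0.44	0.048	synthetic
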