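rsid	gene	ref	alt	f_ref_hom	f_het	f_alt_hom	p_alt	ci_low	ci_high	hwe_p	note
rs1048943	CYP1A1	T	C	0.85	0.14	0.01	0.08	0.05	0.11	0.21
rs1799814	CYP1A1	G	T	0.91	0.09	0.00	0.04	0.02	0.07	0.38
rs1065852	CYP2D6	G	A	0.68	0.28	0.04	0.18	0.14	0.22	0.48
rs28371706	CYP2D6	G	A	0.90	0.10	0.01	0.05	0.03	0.08	0.32
rs11572103	CYP2C8	T	A	0.90	0.09	0.01	0.06	0.03	0.08	0.01
rs10509681	CYP2C8	T	C	0.82	0.17	0.02	0.10	0.07	0.13	0.06
rs1799853	CYP2C9	C	T	0.81	0.18	0.01	0.10	0.07	0.13	0.83
rs1057910	CYP2C9	A	C	0.93	0.06	0.01	0.03	0.01	0.05	0.33
rs2242480	CYP3A4	C	T	0.47	0.40	0.13	0.33	0.28	0.38	0.05
rs2740574	CYP3A4	T	C	0.63	0.29	0.08	0.23	0.73	0.82	0.01
rs776746	CYP3A5	T	C	0.14	0.35	0.52	0.69	0.64	0.74	0.01
rs4244285	CYP2C19	G	A	0.76	0.22	0.02	0.13	0.10	0.17	0.69
rs2234922	EPHX1	A	G	0.64	0.30	0.06	0.21	0.16	0.25	0.07
rs2066853	AHR	G	A	0.61	0.32	0.06	0.22	0.18	0.27	0.24
rs1045642	ABCB1	G	A	0.40	0.45	0.15	0.37	0.32	0.42	0.58
rs140695	MBD4	T	C	0.05	0.34	0.61	0.78	0.73	0.82	0.71
rs603097	MBD2	G	A	0.01	0.23	0.75	0.87	0.83	0.91	0.67
rs11121832	MTHFR	T	C	0.09	0.39	0.53	0.72	0.67	0.77	0.46
rs16828708	MBD5	A	G	0.51	0.40	0.10	0.29	0.25	0.34	0.43
rs2072408	EZH2	A	G	0.04	0.36	0.60	0.78	0.73	0.82	0.54
rs4792953	EZH1	T	C	0.15	0.43	0.42	0.63	0.58	0.68	0.19
rs7359598	EZH1	T	C	0.21	0.47	0.32	0.56	0.50	0.61	0.31
rs3025039	VEGFA	C	T	0.79	0.19	0.03	0.12	0.08	0.15	0.04
rs712829	EGFR	G	T	0.47	0.41	0.11	0.32	0.24	0.41	0.59
rs1042522	TP53	G	C	0.15	0.43	0.41	0.63	0.58	0.68	0.21	TP53 lies on the minus strand; plus-strand G (minus-strand C) encodes Pro72, plus-strand C encodes Arg72
rs13181	ERCC2	T	G	0.51	0.39	0.10	0.29	0.24	0.34	0.34
rs25487	XRCC1	T	C	0.08	0.39	0.53	0.73	0.68	0.77	0.92
rs861539	XRCC3	G	A	0.50	0.37	0.12	0.31	0.26	0.36	0.02
rs10764896	MGMT	G	A	0.21	0.46	0.32	0.56	0.50	0.61	0.25
rs11016798	MGMT	C	T	0.34	0.45	0.21	0.44	0.38	0.49	0.07
rs11016879	MGMT	A	G	0.11	0.46	0.43	0.66	0.61	0.71	0.69
rs11016885	MGMT	T	C	0.53	0.37	0.10	0.28	0.24	0.33	0.10
rs12259379	MGMT	G	T	0.68	0.28	0.04	0.18	0.14	0.22	0.19
rs4751104	MGMT	G	A	0.35	0.46	0.19	0.42	0.37	0.47	0.26
rs12763287	MGMT	T	G	0.81	0.17	0.02	0.11	0.07	0.14	0.09
rs1762429	MGMT	C	T	0.30	0.42	0.27	0.49	0.43	0.54	0.00
rs1762438	MGMT	C	T	0.24	0.51	0.25	0.51	0.45	0.56	0.71
rs4751115	MGMT	T	C	0.15	0.45	0.40	0.62	0.57	0.68	0.38
rs7068306	MGMT	C	G	0.48	0.41	0.10	0.31	0.26	0.36	0.60
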