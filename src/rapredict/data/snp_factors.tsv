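# Non-HLA RA susceptibility SNPs: published meta-analysis per-allele ORs
# (95% CI) and control minor-allele frequencies.
id	kind	resolution	parent	or	ci_low	ci_high	control_freq	n_cases	n_controls	exposure_prev	applies_to
rs2476601	snp			1.94	1.81	2.08	0.10
rs6920220	snp			1.22	1.16	1.29	0.22
rs6859219	snp			0.78	0.72	0.85	0.21
rs4810485	snp			0.85	0.80	0.90	0.25
rs3087243	snp			0.87	0.83	0.91	0.44
rs5029937	snp			1.40	1.24	1.58	0.04
rs706778	snp			1.14	1.09	1.20	0.40
rs874040	snp			1.14	1.08	1.20	0.30
rs3761847	snp			1.13	1.08	1.18	0.43
rs7574865	snp			1.16	1.10	1.23	0.22
rs934734	snp			1.13	1.08	1.19	0.49
rs3093023	snp			1.13	1.08	1.19	0.43
rs13315591	snp			1.29	1.17	1.43	0.09
rs26232	snp			0.88	0.84	0.93	0.32
rs951005	snp			0.84	0.78	0.90	0.16
rs13031237	snp			1.13	1.07	1.18	0.37
rs10865035	snp			1.12	1.07	1.17	0.47
rs4750316	snp			0.87	0.82	0.92	0.19
rs10488631	snp			1.19	1.10	1.28	0.11
rs3890745	snp			0.89	0.85	0.94	0.32
rs11586238	snp			1.13	1.07	1.19	0.24
rs2736340	snp			1.12	1.07	1.18	0.25
rs1980422	snp			1.12	1.06	1.18	0.24
rs548234	snp			1.10	1.05	1.16	0.33
rs2812378	snp			1.10	1.05	1.16	0.34
rs10919563	snp			0.88	0.82	0.94	0.13
rs1678542	snp			0.91	0.87	0.96	0.38
rs540386	snp			0.88	0.83	0.94	0.14
rs12746613	snp			1.13	1.06	1.21	0.12
rs394581	snp			0.91	0.87	0.96	0.30
rs10499194	snp			0.91	0.87	0.96	0.27
rs6822844	snp			0.90	0.84	0.95	0.18
rs2104286	snp			0.92	0.87	0.97	0.27
rs3218253	snp			1.09	1.03	1.15	0.26
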