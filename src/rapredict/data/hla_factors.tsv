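# HLA-DRB1 allele risk factors: published meta-analysis allelic ORs (95% CI)
# and control allele frequencies for ACPA-positive RA.
id	kind	resolution	parent	or	ci_low	ci_high	control_freq	n_cases	n_controls	exposure_prev	applies_to
*01	hla_allele	two_digit		1.30	1.21	1.40	0.113
*01:01	hla_allele	four_digit	*01	1.38	1.28	1.50	0.097
*03	hla_allele	two_digit		0.59	0.54	0.64	0.128
*03:01	hla_allele	four_digit	*03	0.59	0.54	0.64	0.128
*04	hla_allele	two_digit		3.71	3.49	3.93	0.174
*04:01	hla_allele	four_digit	*04	4.14	3.86	4.44	0.104
*04:04	hla_allele	four_digit	*04	3.17	2.83	3.54	0.036
*04:05	hla_allele	four_digit	*04	2.31	1.77	3.01	0.007
*04:08	hla_allele	four_digit	*04	5.48	4.11	7.30	0.005
*07	hla_allele	two_digit		0.49	0.45	0.54	0.133
*07:01	hla_allele	four_digit	*07	0.49	0.45	0.54	0.133
*08	hla_allele	two_digit		0.41	0.34	0.50	0.029
*08:01	hla_allele	four_digit	*08	0.34	0.26	0.44	0.019
*10	hla_allele	two_digit		2.53	2.04	3.14	0.008
*10:01	hla_allele	four_digit	*10	2.53	2.04	3.14	0.008
*11	hla_allele	two_digit		0.48	0.43	0.54	0.094
*11:01	hla_allele	four_digit	*11	0.44	0.38	0.52	0.061
*11:04	hla_allele	four_digit	*11	0.15	0.10	0.23	0.024
*13	hla_allele	two_digit		0.33	0.30	0.37	0.114
*13:01	hla_allele	four_digit	*13	0.28	0.24	0.33	0.061
*13:02	hla_allele	four_digit	*13	0.29	0.23	0.38	0.027
*14	hla_allele	two_digit		0.50	0.40	0.62	0.025
*14:01	hla_allele	four_digit	*14	0.46	0.36	0.59	0.022
*15	hla_allele	two_digit		0.59	0.54	0.64	0.142
*15:01	hla_allele	four_digit	*15	0.57	0.53	0.62	0.136
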