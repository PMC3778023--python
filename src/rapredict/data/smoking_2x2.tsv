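cohort	sex	case_exposed	case_unexposed	control_exposed	control_unexposed
WTCCC	male	231	56	422	317
UKRAGG	male	417	112	149	173
WTCCC	female	552	395	425	311
UKRAGG	female	758	597	238	368
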