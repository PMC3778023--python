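# Environmental risk factor: male ever-smoking (meta-analysis OR for
# seropositive RA); exposure prevalence = ever-smoking fraction among the
# larger cohort's male controls.
id	kind	resolution	parent	or	ci_low	ci_high	control_freq	n_cases	n_controls	exposure_prev	applies_to
ever_smoking_male	environment			3.02	2.35	3.88				0.571	males
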