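dose_midpoint,n_subjects,n_cases
0,35804,18
65,31923,13
388,24605,25
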