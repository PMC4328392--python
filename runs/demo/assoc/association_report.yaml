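count_pseudocount: 1.0
density_pseudocount: 0.0001
infection_form: log_ratio
n: 7
p: 2.478527200072725e-06
r: 0.9955872745124064
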