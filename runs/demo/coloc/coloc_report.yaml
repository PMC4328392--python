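degenerate: false
mean_control_peak_r: 0.009353119319834416
mean_peak_dx_px: 0.0
mean_peak_r: 0.32586182367788424
n_samples: 20
p_value: 7.447054321348697e-32
paired_t: 173.1606955314676
sem_peak_dx_px: 0.0
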