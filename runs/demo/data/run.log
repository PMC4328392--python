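INFO fiberlayer: synthesized animal_01 (densities {'GCL': 0.0008730929285813103, 'EPL': 0.000668717258063934, 'GL': 0.014002130128267147})
INFO fiberlayer: synthesized animal_02 (densities {'GCL': 0.0008730929285813103, 'EPL': 0.000668717258063934, 'GL': 0.01396395827413804})
INFO fiberlayer: synthesized animal_03 (densities {'GCL': 0.0008730929285813103, 'EPL': 0.000668717258063934, 'GL': 0.013988249454038381})
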