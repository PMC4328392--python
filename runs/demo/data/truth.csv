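animal,layer,true_density_um2_per_100um2,n_fibers
animal_01,GCL,0.0008730929285813103,4
animal_01,EPL,0.000668717258063934,6
animal_01,GL,0.014002130128267147,193
animal_02,GCL,0.0008730929285813103,4
animal_02,EPL,0.000668717258063934,6
animal_02,GL,0.01396395827413804,192
animal_03,GCL,0.0008730929285813103,4
animal_03,EPL,0.000668717258063934,6
animal_03,GL,0.013988249454038381,192
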