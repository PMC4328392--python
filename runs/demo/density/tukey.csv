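layer_a,layer_b,meandiff,p_adj,lower,upper,reject
EPL,GCL,0.0003,0.615,-0.0007,0.0014,False
EPL,GL,0.0148,0.0,0.0138,0.0159,True
GCL,GL,0.0145,0.0,0.0134,0.0155,True
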