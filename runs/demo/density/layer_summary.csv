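layer,mean,sem,n
EPL,0.0003968253968253969,0.00026247532847863,3
GCL,0.0007322373393801965,8.672316586680752e-05,3
GL,0.01521636432350718,0.0003154560851246512,3
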