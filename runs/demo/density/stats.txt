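Layer-density comparison (unit: animal; density in um^2/100 um^2)

one-way ANOVA across layers: F = 1221, p = 1.473e-08

layer     mean      sem  n
  EPL 0.000397 0.000262  3
  GCL 0.000732 0.000087  3
   GL 0.015216 0.000315  3

layer_a layer_b  meandiff  p_adj   lower  upper  reject
    EPL     GCL    0.0003  0.615 -0.0007 0.0014   False
    EPL      GL    0.0148  0.000  0.0138 0.0159    True
    GCL      GL    0.0145  0.000  0.0134 0.0155    True
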