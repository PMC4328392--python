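layer,sector_index,center_row_px,center_col_px,side_px,resolution_px_per_um
GCL,0,4074,5225,840,7.0
GCL,1,3810,4636,840,7.0
GCL,2,3294,3989,840,7.0
GCL,3,3601,4000,840,7.0
GCL,4,3808,3527,840,7.0
GCL,5,4288,4242,840,7.0
GCL,6,4507,4173,840,7.0
GCL,7,5374,4228,840,7.0
GCL,8,4800,4902,840,7.0
GCL,9,4386,4635,840,7.0
EPL,0,3574,6492,840,7.0
EPL,1,2153,5392,840,7.0
EPL,2,1835,3969,840,7.0
EPL,3,2236,3197,840,7.0
EPL,4,4021,1878,840,7.0
EPL,5,4905,2098,840,7.0
EPL,6,6422,3189,840,7.0
EPL,7,6554,3872,840,7.0
EPL,8,6351,5478,840,7.0
EPL,9,5216,6523,840,7.0
GL,0,3932,7935,840,7.0
GL,1,1009,5899,840,7.0
GL,2,696,5178,840,7.0
GL,3,1580,1801,840,7.0
GL,4,3726,688,840,7.0
GL,5,4729,598,840,7.0
GL,6,7516,2591,840,7.0
GL,7,7816,3157,840,7.0
GL,8,6903,6807,840,7.0
GL,9,5590,7626,840,7.0
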