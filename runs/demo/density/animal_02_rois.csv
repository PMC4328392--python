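layer,sector_index,center_row_px,center_col_px,side_px,resolution_px_per_um
GCL,0,4083,4906,840,7.0
GCL,1,3373,4966,840,7.0
GCL,2,3466,4114,840,7.0
GCL,3,3888,3829,840,7.0
GCL,4,4230,3928,840,7.0
GCL,5,4336,3422,840,7.0
GCL,6,4729,4089,840,7.0
GCL,7,5052,4370,840,7.0
GCL,8,5237,4816,840,7.0
GCL,9,4343,5536,840,7.0
EPL,0,4201,6758,840,7.0
EPL,1,2256,5573,840,7.0
EPL,2,2014,3741,840,7.0
EPL,3,2411,2882,840,7.0
EPL,4,4112,2109,840,7.0
EPL,5,5089,2037,840,7.0
EPL,6,5801,2436,840,7.0
EPL,7,6516,4208,840,7.0
EPL,8,6134,5727,840,7.0
EPL,9,4666,6533,840,7.0
GL,0,4199,8009,840,7.0
GL,1,1087,6034,840,7.0
GL,2,760,4772,840,7.0
GL,3,1461,2019,840,7.0
GL,4,3753,594,840,7.0
GL,5,4501,659,840,7.0
GL,6,7500,2693,840,7.0
GL,7,7753,3858,840,7.0
GL,8,7619,5462,840,7.0
GL,9,4849,7890,840,7.0
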