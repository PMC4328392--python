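layer,sector_index,center_row_px,center_col_px,side_px,resolution_px_per_um
GCL,0,3690,5202,840,7.0
GCL,1,3694,4776,840,7.0
GCL,2,3768,4344,840,7.0
GCL,3,3512,3756,840,7.0
GCL,4,4107,3062,840,7.0
GCL,5,4678,3660,840,7.0
GCL,6,5112,3659,840,7.0
GCL,7,5268,4481,840,7.0
GCL,8,4805,4886,840,7.0
GCL,9,4425,4485,840,7.0
EPL,0,4280,6640,840,7.0
EPL,1,2611,5946,840,7.0
EPL,2,2037,4778,840,7.0
EPL,3,2193,3095,840,7.0
EPL,4,3594,2099,840,7.0
EPL,5,4301,1906,840,7.0
EPL,6,6295,2994,840,7.0
EPL,7,6656,3940,840,7.0
EPL,8,6469,5180,840,7.0
EPL,9,4289,6792,840,7.0
GL,0,3117,7672,840,7.0
GL,1,1641,6835,840,7.0
GL,2,814,4724,840,7.0
GL,3,1502,1894,840,7.0
GL,4,3360,665,840,7.0
GL,5,4338,550,840,7.0
GL,6,7685,3029,840,7.0
GL,7,8043,4176,840,7.0
GL,8,7141,6559,840,7.0
GL,9,6164,7454,840,7.0
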