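animal,layer,detected_px,total_px,density_um2_per_100um2,resolution_px_per_um
animal_01,GCL,63,7056000,0.0008928571428571428,7.0
animal_01,EPL,63,7056000,0.0008928571428571428,7.0
animal_01,GL,1106,7056000,0.015674603174603174,7.0
animal_02,GCL,50,7056000,0.0007086167800453515,7.0
animal_02,EPL,21,7056000,0.00029761904761904765,7.0
animal_02,GL,1031,7056000,0.014611678004535148,7.0
animal_03,GCL,42,7056000,0.0005952380952380953,7.0
animal_03,EPL,0,7056000,0.0,7.0
animal_03,GL,1084,7056000,0.01536281179138322,7.0
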