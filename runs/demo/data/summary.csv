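animal,injection_target,n_drn,n_mrn,d_gl,d_epl,d_gcl
animal_01,DRN,182,17,0.002589528647597348,0.0021139385324116175,0.006974857410141651
animal_02,DRN,260,5,0.0011856590283329902,0.0022547277286088132,0.0099561175846868
animal_03,DRN,276,14,0.002351971864832658,0.003344732570478944,0.010758241539110276
animal_04,DRN,354,3,0.0014235101509449803,0.003688089698837492,0.015153014579647989
animal_05,MRN,29,103,0.011269074097141034,0.0019282875895200698,0.0013511869865057053
animal_06,MRN,105,125,0.01317215384560071,0.0036318872721820385,0.00482929380065646
animal_07,MRN,114,92,0.010417079973804725,0.002394896489566876,0.00395469478640046
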