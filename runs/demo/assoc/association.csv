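animal,injection_target,n_drn,n_mrn,d_gl,d_epl,d_gcl,infection_ratio,abundance_ratio
animal_01,DRN,182,17,0.0025895286475973,0.0021139385324116,0.0069748574101416,-1.0071785846271235,-0.42004151677464274
animal_02,DRN,260,5,0.0011856590283329,0.0022547277286088,0.0099561175846868,-1.6384892569546374,-0.8933045389166964
animal_03,DRN,276,14,0.0023519718648326,0.0033447325704789,0.0107582415391102,-1.2663885100087673,-0.6462440156488987
animal_04,DRN,354,3,0.0014235101509449,0.0036880896988374,0.0151530145796479,-1.9481683617271317,-1.0005103331680958
animal_05,MRN,29,103,0.011269074097141,0.00192828758952,0.0013511869865057,0.5399120845791179,0.8940017217713501
animal_06,MRN,105,125,0.0131721538456007,0.003631887272182,0.0048292938006564,0.07506467985279265,0.43015670304026316
animal_07,MRN,114,92,0.0104170799738047,0.0023948964895668,0.0039546947864004,-0.09221489179967657,0.4139370077458738
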