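strain,chlorophyta,surviving,coverage_t0_pct,coverage_t10_pct
Aulosira terrestre,False,False,6.04,1.43
Calothrix membranacea,False,True,49.54,32.57
Chlorella vulgaris,True,False,95.68,0.49
Coccomyxa solorinae-saccatae,True,False,67.25,4.39
Coelastrella rubescens,True,True,70.34,71.00
Fischerella ambigua,False,True,92.54,19.13
Microchaete diplosiphon,False,True,95.08,88.50
Microcoleus autumnalis,False,True,99.17,97.20
Nodularia sphaerocarpa,False,True,67.25,18.00
Nostoc commune,False,True,81.80,86.00
Plectonema sp.,False,True,85.67,88.20
Pseudococcomyxa simplex,True,False,94.91,3.89
Scenedesmus communis,True,False,56.37,14.92
Scytonema mirabile,False,False,13.09,9.47
Stichococcus bacillaris,True,False,99.32,12.57
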