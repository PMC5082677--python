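strain,op_max,op_mean,op_weighted
Calothrix membranacea,0.323837,0.260432,0.275539
Coelastrella rubescens,0.398235,0.304611,0.319582
Fischerella ambigua,0.345014,0.277347,0.293566
Microchaete diplosiphon,0.423429,0.292897,0.327389
Microcoleus autumnalis,0.309799,0.276611,0.282816
Nodularia sphaerocarpa,0.347104,0.275312,0.288315
Nostoc commune,0.533988,0.389427,0.417707
Plectonema sp.,0.494467,0.36662,0.399202
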