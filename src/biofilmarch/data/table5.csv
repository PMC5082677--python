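strain,op_max,op_mean,op_weighted
Calothrix membranacea,0.410930,0.423024,0.425755
Coelastrella rubescens,0.576164,0.513284,0.507068
Fischerella ambigua,0.428324,0.424578,0.430884
Nostoc commune,0.988081,1.0,0.996889
Plectonema sp.,0.78864,0.800178,0.82809
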