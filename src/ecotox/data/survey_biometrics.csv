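species,site,n,length_mean,length_sd,length_min,length_max,weight_mean,weight_sd,weight_min,weight_max
species_A,urban,15,19,1.72,17,21,96,10.15,83,110
species_B,rural,15,12,0.68,10.8,13,38,6.88,28,57
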