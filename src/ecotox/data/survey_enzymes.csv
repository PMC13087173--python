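species,site,enzyme,tissue,mean,sd,min,max
species_A,urban,AChE,muscle,19207,9794,12263.87,38376.78
species_A,urban,AChE,liver,15372.55,3405,12263.87,18481.23
species_A,urban,AST,liver,294.39,88,191.29,410.22
species_A,urban,ALT,liver,528.89,260,94.41,822.14
species_A,urban,ALP,muscle,121.72,96,18.77,274.64
species_A,urban,ALP,liver,471.13,74,384.68,604.78
species_B,rural,AChE,muscle,2544,1071,1818.71,3994.78
species_B,rural,AChE,liver,2352.36,991,1818.71,3994.78
species_B,rural,AST,liver,290.02,152,115.26,430.38
species_B,rural,ALT,liver,38.28,3,35.18,41.95
species_B,rural,ALP,muscle,89.39,25,82.05,170.09
species_B,rural,ALP,liver,104.06,40,82.05,170.09
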