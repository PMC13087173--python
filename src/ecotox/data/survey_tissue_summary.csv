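species,site,tissue,element,mean,sd,min,max,detection_limit
species_A,urban,muscle,Al,7.19,4.49,2.27,13.27,0.014
species_A,urban,liver,Al,3.34,2.36,1.21,6.93,0.014
species_A,urban,muscle,As,1.83,0.65,1.06,2.75,0.002
species_A,urban,liver,As,1.60,0.41,0.96,1.99,0.002
species_A,urban,muscle,Au,0.71,0.37,0.35,1.31,0.001
species_A,urban,liver,Au,3.95,2.71,0.62,7.44,0.001
species_A,urban,muscle,Cr,1.83,1.15,0.78,3.70,0.003
species_A,urban,liver,Cr,,,,,0.003
species_A,urban,muscle,In,0.31,0.17,0.19,2.31,0.033
species_A,urban,liver,In,,,,,0.033
species_A,urban,muscle,Pb,,,,,0.012
species_A,urban,liver,Pb,3.90,2.53,1.44,6.74,0.012
species_A,urban,muscle,Ni,2.53,1.04,1.85,3.18,0.002
species_A,urban,liver,Ni,2.66,0.59,1.76,3.20,0.002
species_A,urban,muscle,Ba,0.31,0.25,0.13,0.48,0.002
species_A,urban,liver,Ba,0.14,0.18,0.13,0.36,0.002
species_A,urban,muscle,Ca,590.14,132.36,77.38,759.31,0.007
species_A,urban,liver,Ca,394.70,128.16,139.04,489.09,0.007
species_A,urban,muscle,Co,,,,,0.003
species_A,urban,liver,Co,5.54,2.01,3.60,7.80,0.003
species_A,urban,muscle,Cu,0.31,0.20,0.14,0.66,0.003
species_A,urban,liver,Cu,9.56,3.10,6.52,13.71,0.003
species_A,urban,muscle,S,298.79,34.68,274.54,368.13,0.001
species_A,urban,liver,S,210.57,46.19,168.36,274.54,0.001
species_A,urban,muscle,Se,9.30,4.13,5.24,15.62,0.024
species_A,urban,liver,Se,13.91,3.92,8.51,17.93,0.024
species_A,urban,muscle,Sb,1.94,0.59,1.23,2.78,0.003
species_A,urban,liver,Sb,3.12,1.00,1.64,4.09,0.003
species_A,urban,muscle,Sn,6.97,2.20,5.16,10.60,0.021
species_A,urban,liver,Sn,6.15,1.29,4.31,7.40,0.021
species_A,urban,muscle,Si,9.44,3.00,6.34,14.98,0.015
species_A,urban,liver,Si,15.04,3.39,11.40,19.64,0.015
species_A,urban,muscle,Fe,11.07,5.10,7.64,20.92,0.002
species_A,urban,liver,Fe,1215.93,703.10,432.88,2189.80,0.002
species_A,urban,muscle,Mg,212.47,32.12,169.09,249.19,0.001
species_A,urban,liver,Mg,150.45,9.22,142.02,163.00,0.001
species_A,urban,muscle,Mn,1.04,1.28,0.18,3.55,0.001
species_A,urban,liver,Mn,1.47,0.21,1.11,1.62,0.001
species_A,urban,muscle,Na,186.90,24.31,163.76,229.39,0.020
species_A,urban,liver,Na,202.42,73.23,149.90,305.07,0.020
species_A,urban,muscle,P,2.67,2.01,0.89,6.40,0.004
species_A,urban,liver,P,17.33,3.70,12.95,22.54,0.004
species_A,urban,muscle,K,257.33,26.53,207.45,284.86,0.018
species_A,urban,liver,K,384.88,110.41,280.22,572.73,0.018
species_A,urban,muscle,Zn,3.99,4.25,0.085,9.30,0.002
species_A,urban,liver,Zn,21.72,3.52,17.04,26.73,0.002
species_B,rural,muscle,Al,13.06,3.99,5.27,19.60,0.014
species_B,rural,liver,Al,1.82,1.24,0.58,3.52,0.014
species_B,rural,muscle,As,2.85,0.70,0.30,6.70,0.002
species_B,rural,liver,As,,,,,0.002
species_B,rural,muscle,Au,1.26,0.27,0.66,4.25,0.001
species_B,rural,liver,Au,0.39,0.48,0.004,1.23,0.001
species_B,rural,muscle,Cr,3.61,3.22,0.31,12.85,0.003
species_B,rural,liver,Cr,,,,,0.003
species_B,rural,muscle,In,2.33,1.19,0.10,4.30,0.033
species_B,rural,liver,In,,,,,0.033
species_B,rural,muscle,Pb,,,,,0.012
species_B,rural,liver,Pb,,,,,0.012
species_B,rural,muscle,Ni,3.32,1.04,0.37,6.56,0.002
species_B,rural,liver,Ni,,,,,0.002
species_B,rural,muscle,Ba,1.92,0.61,0.22,11.82,0.002
species_B,rural,liver,Ba,,,,,0.002
species_B,rural,muscle,Ca,20757.30,11173.31,951.68,87608.17,0.007
species_B,rural,liver,Ca,183.52,55.35,113.92,265.08,0.007
species_B,rural,muscle,Co,,,,,0.003
species_B,rural,liver,Co,,,,,0.003
species_B,rural,muscle,Cu,0.79,0.50,0.16,1.90,0.003
species_B,rural,liver,Cu,0.83,0.81,0.37,2.60,0.003
species_B,rural,muscle,S,401.42,73.46,281.74,536.63,0.001
species_B,rural,liver,S,44.15,24.72,23.94,95.24,0.001
species_B,rural,muscle,Se,15.94,10.55,9.98,46.59,0.024
species_B,rural,liver,Se,,,,,0.024
species_B,rural,muscle,Sb,3.12,1.39,1.62,6.94,0.003
species_B,rural,liver,Sb,,,,,0.003
species_B,rural,muscle,Sn,12.19,8.74,8.24,37.93,0.021
species_B,rural,liver,Sn,,,,,0.021
species_B,rural,muscle,Si,9.47,2.74,6.98,14.40,0.015
species_B,rural,liver,Si,10.65,1.99,8.71,13.72,0.015
species_B,rural,muscle,Fe,12.11,4.06,1.65,18.56,0.002
species_B,rural,liver,Fe,229.66,230.99,30.22,683.70,0.002
species_B,rural,muscle,Mg,258.76,104.69,32.78,496.50,0.001
species_B,rural,liver,Mg,18.54,9.15,11.01,36.26,0.001
species_B,rural,muscle,Mn,1.29,1.12,0.04,4.22,0.001
species_B,rural,liver,Mn,0.35,0.16,0.14,0.58,0.001
species_B,rural,muscle,Na,173.21,58.57,25.99,631.91,0.020
species_B,rural,liver,Na,67.90,18.14,42.82,91.74,0.020
species_B,rural,muscle,P,4.85,1.89,3.66,9.21,0.004
species_B,rural,liver,P,,,,,0.004
species_B,rural,muscle,K,470.27,176.74,138.49,694.83,0.018
species_B,rural,liver,K,230.35,231.09,30.22,685.56,0.018
species_B,rural,muscle,Zn,11.86,8.55,1.65,13.94,0.002
species_B,rural,liver,Zn,1.37,1.22,0.16,28.20,0.002
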