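element,site,tissue,bcf
Al,urban,muscle,10.42
Al,urban,liver,4.84
Al,rural,muscle,20.71
Al,rural,liver,2.89
Au,urban,muscle,8.88
Au,urban,liver,49.38
Au,rural,muscle,12.60
Au,rural,liver,3.90
In,urban,muscle,0.53
In,rural,muscle,4.57
Ca,urban,muscle,71.63
Ca,urban,liver,47.91
Ca,rural,muscle,1648.62
Ca,rural,liver,14.58
Cu,urban,muscle,6.20
Cu,urban,liver,191.20
Cu,rural,muscle,15.80
Cu,rural,liver,16.60
Fe,urban,muscle,24.07
Fe,urban,liver,2641.30
Fe,rural,muscle,11.87
Fe,rural,liver,225.16
Na,urban,muscle,203.15
Na,urban,liver,219.15
Na,rural,muscle,151.06
Na,rural,liver,59.56
K,urban,muscle,536.10
K,urban,liver,801.83
K,rural,muscle,723.49
K,rural,liver,354.38
S,urban,muscle,1757.59
S,urban,liver,1239.82
S,rural,muscle,2867.29
S,rural,liver,315.36
Se,urban,muscle,46.50
Se,urban,liver,69.55
Se,rural,muscle,93.76
Sn,urban,muscle,25.81
Sn,urban,liver,22.78
Sn,rural,muscle,35.85
Si,urban,muscle,2.12
Si,urban,liver,3.37
Si,rural,muscle,1.36
Si,rural,liver,1.53
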