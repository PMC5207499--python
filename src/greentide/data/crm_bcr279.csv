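metal,reported_mean,reported_unc,found_mean,found_unc,certified
As,3.09,0.21,3.24,0.19,1
Cd,0.27,0.02,0.24,0.02,1
Cu,13.10,0.40,12.38,0.79,1
Pb,13.50,0.40,13.17,5.10,1
Se,5.90,0.40,5.14,1.79,1
Zn,51.30,1.20,51.86,9.49,1
Cr,10.73,0.70,9.61,0.80,0
Mn,2090.00,50.00,2245.07,270.93,0
Ni,15.90,0.40,13.90,1.83,0
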