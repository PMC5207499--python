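metal,Tolka,Dungarvan,Courtmacsherry,Clonakilty,Spiddal,Murrisk,Moy,New Quay
Al,1081.55,1591.43,548.75,509.79,23.45,336.81,234.93,90.58
Ti,23.52,25.29,13.11,18.38,7.62,13.09,14.48,9.08
Mn,128.56,131.56,212.06,144.57,25.58,125.95,20.71,15.81
Co,0.85,0.78,0.66,0.72,0.14,0.57,0.31,0.09
Zn,31.71,31.38,17.21,24.70,10.84,26.45,17.68,12.59
Se,2.67,2.94,2.92,3.05,5.53,4.04,3.93,2.51
Sr,71.19,97.33,91.72,114.70,90.93,94.45,78.00,73.99
Mo,0.22,0.13,0.10,0.14,0.11,0.10,0.07,0.09
Ba,5.83,5.98,3.22,6.51,0.30,4.24,3.72,1.59
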