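metal,Tolka,Dungarvan,Courtmacsherry,Clonakilty,Spiddal,Murrisk,Moy,New Quay
Al,116.80,294.72,86.33,96.50,6.18,57.24,47.29,21.54
Ti,1.90,3.71,1.09,2.27,0.35,1.49,1.53,0.42
Mn,30.82,24.73,57.64,49.87,4.28,25.50,2.26,2.29
Co,0.05,0.07,0.06,0.09,0.01,0.04,0.02,0.01
Zn,1.71,3.11,1.18,1.61,0.31,2.40,1.37,0.34
Se,0.24,0.26,0.29,0.43,0.57,0.40,0.50,0.23
Sr,4.34,7.86,4.85,5.09,2.73,2.95,4.59,4.63
Mo,0.02,0.01,0.01,0.02,0.01,0.01,0.01,0.01
Ba,0.54,1.08,0.34,0.79,0.04,0.46,0.27,0.39
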