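metal,spearman_rho
Al,-0.554
Ti,-0.590
V,-0.337
Cr,-0.313
Mn,-0.735
Ni,-0.193
Co,-0.530
Cu,-0.590
Zn,-0.277
As,-0.229
Se,0.084
Sr,-0.470
Mo,-0.193
Ag,-0.036
Cd,-0.327
Sn,-0.602
Sb,-0.627
Ba,-0.554
Tl,-0.313
Pb,-0.602
Bi,-0.602
MCI,-0.530
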