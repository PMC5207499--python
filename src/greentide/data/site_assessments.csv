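site_id,status,eqr,spatial_cover_ha,mean_biomass_g_m2,total_biomass_t
Tolka,Moderate,0.57,40.63,1329.53,540.19
Dungarvan,Moderate,0.54,108.71,302.50,328.85
Courtmacsherry,Poor,0.38,128.78,1680.51,2164.16
Clonakilty,Poor,0.38,76.12,1110.42,845.25
Spiddal,High,1,,,
Murrisk,High,0.93,28.57,,
Moy,Moderate,0.47,98.99,402.00,397.94
New Quay,High,1,,,
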