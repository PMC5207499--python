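"""Relate tissue metal concentrations to site EQR.

Uses the shipped per-site mean concentrations and published EQRs:
tie-corrected Spearman per metal, then a Fisher-z average across metals,
plus the Metal Content Index of one site.
"""

import greentide as gt

means = gt.datasets.load_metal_site_means()          # site x metal, mg/kg dw
sites = gt.datasets.load_site_assessments().set_index("site_id")
eqr = sites.loc[means.index, "eqr"].astype(float)

print("metal   rho      p")
rhos = []
for metal in means.columns:
    r = gt.spearman(means[metal].values, eqr.values, name=metal)
    rhos.append(r.coefficient)
    print(f"{metal:<6} {r.coefficient:+.3f}  {r.p_value:.3f}")

mean_r, lo, hi = gt.fisher_z_mean(rhos)
print(f"\nFisher-z mean over these metals: {mean_r:+.3f} (95% CI {lo:+.3f} to {hi:+.3f})")
print("negative mean: metal burdens tend to rise as ecological status falls")

mci = gt.metal_content_index(means.loc["Dungarvan"].values)
print(f"Metal Content Index (geometric mean), Dungarvan: {mci:.2f} mg/kg dw")
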