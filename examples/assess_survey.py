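"""Score a synthetic bloom survey to an EQR and Ecological Status class.

Generates a survey targeting 'Moderate' status, reduces it to the five
sub-metrics and scores it against the boundary table.
"""

import greentide as gt

table = gt.datasets.load_boundary_table()
survey, truth = gt.generate_survey(
    gt.SurveyScenario(target_status="Moderate", seed=42))
result = gt.assess_site(survey, table)

sm = result.submetrics
print(f"site: {result.site_id}  ({len(survey.quadrats)} quadrats, "
      f"{len(survey.geometry.patch_areas_ha)} patches, "
      f"AIH {survey.geometry.aih_ha:.1f} ha)")
print(f"  cover of AIH:      {sm.cover_pct_aih:8.2f} %")
print(f"  affected area:     {sm.aa_ha:8.2f} ha ({sm.aa_over_aih_pct:.1f}% of AIH)")
print(f"  biomass over AA:   {sm.biomass_aa_g_m2:8.1f} g/m2 wet weight")
print(f"  biomass over AIH:  {sm.biomass_aih_g_m2:8.1f} g/m2")
print(f"  quadrats entrained:{sm.entrained_pct:8.1f} %")
for name, eqr in sorted(result.sub_eqrs.items()):
    print(f"  EQR[{name}] = {eqr:.3f}")
print(f"final EQR {result.final_eqr:.2f} -> {result.status} "
      f"(generator expected {truth.final_eqr:.2f}, {truth.status})")
# The final EQR is the mean of the five sub-metric scores; 0.4-0.6 is the
# Moderate band, i.e. a water body failing its WFD objective.
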