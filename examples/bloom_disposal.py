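"""Cost and metal-load arithmetic for collecting a bloom, plus regulatory
screening of its tissue concentrations."""

import greentide as gt
from greentide.management import ARABLE_EUR_PER_TONNE, LANDFILL_EUR_PER_TONNE

inv = gt.BloomInventory("Courtmacsherry", wet_tonnes=2164.16)
print(f"{inv.site_id}: {inv.wet_tonnes:.2f} t wet = {inv.dry_tonnes:.2f} t dry "
      f"(moisture {inv.moisture_fraction:.1%})")
print(f"  landfill disposal (€{LANDFILL_EUR_PER_TONNE:.0f}/t): "
      f"€{gt.disposal_cost(inv.wet_tonnes, LANDFILL_EUR_PER_TONNE):,}")
print(f"  arable-land disposal (€{ARABLE_EUR_PER_TONNE:.0f}/t): "
      f"€{gt.disposal_cost(inv.wet_tonnes, ARABLE_EUR_PER_TONNE):,}")

means = gt.datasets.load_metal_site_means()
conc = means.loc[inv.site_id].to_dict()
print("\nwhole-bloom metal loads if collected:")
for metal, c in list(conc.items())[:5]:
    print(f"  {metal:<3} {gt.metal_load(inv.dry_tonnes, c):8.2f} kg "
          f"(at {c:.2f} mg/kg dw)")

limits = gt.datasets.load_regulatory_limits()
rows = gt.screen_limits(conc, limits)
exceed = [r for r in rows if r["status"] == "exceed" and r["comparable"]]
print(f"\nregulatory screening: {len(rows)} comparisons, "
      f"{len(exceed)} exceedances of directly comparable limits")
for r in exceed:
    print(f"  {r['metal']} {r['concentration_mg_kg']:.2f} mg/kg > "
          f"{r['limit_mg_kg']} ({r['jurisdiction']}, {r['commodity']})")

crm = gt.crm_check(gt.datasets.load_crm_records())
print(f"\nCRM recovery check (BCR-279): {sum(crm.values())}/{len(crm)} metals "
      "within 2x combined uncertainty")
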