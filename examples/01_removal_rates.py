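"""Dung removal rates from pat weights, with evaporation correction.

A pat starts at 300 g wet.  After 48 h in the field it has lost water
(evaporation) and dry mass (beetle activity).  The removal rate is the
dry mass the beetles took: the initial dry mass — estimated through the
water proportion of mesh-covered control pats — minus the final dry mass.
"""

import pandas as pd

from dungbef.dung_removal import site_removal

units = pd.DataFrame([
    # unit_id, role, initial wet (g), final wet (g), final dry (g)
    ("E01", "experimental", 300.0, 120.0, 30.0),
    ("E02", "experimental", 300.0, 160.0, 40.0),
    ("E03", "experimental", 300.0,  90.0, 22.0),
    ("E04", "experimental", 300.0, 200.0, 50.0),
    ("C01", "control",      300.0, 250.0, 62.0),
    ("C02", "control",      300.0, 245.0, 61.5),
], columns=["unit_id", "role", "iw_wet", "fw_wet", "fw_dry"])

results, summary = site_removal(units, mode="control")
print(results.round(2).to_string(index=False))
print(f"\nsite mean removal: {summary['mean_drr']:.1f} g dry / 48 h "
      f"(SD {summary['sd_drr']:.1f}, n = {summary['n']})")
print("Each 'drr' is grams of dry dung removed from that pat; the control "
      "pats only set the shared water-proportion correction (wp).")
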