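"""Liquid-handling arithmetic for working-cell-bank preparation and use.

Every transfer in the automated workflow is exact volume-weighted mixing;
this script walks the standard cryo-culture dilutions.
"""

from mbrtwin.mass_balance import Mixture, inoculate, mix

# Banking: equal volumes of an OD 30 harvest and 50% (w/v) glycerol stock
bank = mix(Mixture(1000, {"biomass_od": 30.0}),
           Mixture(1000, {"glycerol_pct": 50.0}))
print(f"cell bank: OD {bank.conc('biomass_od'):.1f}, "
      f"glycerol {bank.conc('glycerol_pct'):.1f}% (w/v)")

# Thawing aid: equal-volume warm saline halves the glycerol of an MTP bank
thawed = mix(Mixture(100, {"glycerol_pct": 25.0, "biomass_od": 8.0}),
             Mixture(100, {}))
print(f"after saline addition: glycerol {thawed.conc('glycerol_pct'):.1f}%, "
      f"OD {thawed.conc('biomass_od'):.1f}")

# Tube banks frozen at OD 20 are diluted 1:5 before use; glycerol co-dilutes
tube = mix(Mixture(100, {"biomass_od": 20.0, "glycerol_pct": 25.0}),
           Mixture(400, {}))
print(f"tube bank diluted 1:5: OD {tube.conc('biomass_od'):.1f}, "
      f"glycerol {tube.conc('glycerol_pct'):.1f}%")

# Inoculation: 20 µL of the OD 4 suspension into 780 µL medium
od0 = inoculate(stock_od=4.0, v_transfer_uL=20.0, v_medium_uL=780.0)
print(f"preculture starts at OD {od0:.3f}")
print("-> the well begins cultivation at OD 0.1, the standard inoculum "
      "density for reproducible batch times")
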