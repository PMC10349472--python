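"""Clean-in-place: disinfectant carry-over arithmetic and both protocols.

A used well keeps ~10 µL of residual liquid after optimised aspiration.
Repeated 700 µL washes dilute the residue geometrically; two washes push
pure disinfectant below 0.02% (v/v). The two full protocols differ in how
the residue is cleared: medium washes (~2 h) or methanol + evaporation
(~11 h).
"""

from mbrtwin.mass_balance import Mixture, residual_chain
from mbrtwin.orchestration import WellRole, WellState, run_cip

chain = residual_chain(c0=100.0, residual_uL=10.0, wash_uL=700.0, n_washes=3)
print("residual disinfectant after each 700 µL wash (10 µL residual):")
for _, row in chain.to_frame().iterrows():
    print(f"  wash {int(row['step'])}: {row['concentration']:.4g}% (v/v)")
print("-> two washes already beat the 0.02% carry-over target\n")


def dirty_plate():
    return {
        f"W{i}": WellState(role=WellRole.MAIN, harvested=True,
                           mixture=Mixture(100, {"biomass_od": 5.0}))
        for i in range(3)
    }


for protocol in ("medium_wash", "methanol"):
    wells = dirty_plate()
    res = run_cip(wells, protocol=protocol)
    w = wells["W0"]
    print(f"{protocol}: elapsed {res.elapsed_h:.2f} h, "
          f"final disinfectant {res.final_disinfectant_pct('W0'):.3g}%, "
          f"viable={w.viable}, volume {w.mixture.volume_uL:.0f} µL")
print("-> both protocols kill the residual biomass; the medium wash "
      "hands back a refilled, cultivation-ready well in about 2 h")
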