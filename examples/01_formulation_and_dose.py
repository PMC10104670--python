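"""Formulation arithmetic: from emulsion feed to injected drug amount.

A 2 mg ATRA : 100 mg PLGA feed at 62.4% encapsulation efficiency gives the
drug weight fraction of the finished particles; a 2 µg particle dose then
carries a definite payload, which dissolved instantly in the ~20 µL mouse
synovial fluid would give the printed bolus concentration.
"""

from depotpk import (
    DoseSpec,
    FormulationSpec,
    bolus_concentration,
    dose_to_drug_amount,
    loading_weight_fraction,
)

spec = FormulationSpec(
    polymer_mass=100.0, drug_feed_mass=2.0, encapsulation_efficiency=0.624
)
w = loading_weight_fraction(spec)
print(f"drug loading: {100 * w:.2f} wt%")

dose = DoseSpec(mp_mass=2.0, synovial_volume=20.0)
payload = dose_to_drug_amount(dose, w)
print(f"2 ug dose carries {payload['mass_ng']:.1f} ng = {payload['amount_pmol']:.1f} pmol")

c = bolus_concentration(payload["amount_pmol"], dose.synovial_volume)
print(f"instant-release bolus in 20 uL: {c * 1e6:.2f} uM")
print("(the depot releases this payload over ~a month instead)")
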