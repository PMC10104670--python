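"""Centralised unit conversions.

All internal computation uses a single convention:

* time        — hours
* amounts     — pmol
* masses      — as declared per field (mg for formulation feeds, µg for
                injected microparticle doses, ng for drug payloads)
* volumes     — µL for the synovial compartment, mL for the distribution
                volume; converted to litres only when forming molarities
* concentrations — mol/L

Keeping every factor here avoids scattered powers of ten in the science
modules.
"""

HOURS_PER_DAY = 24.0

UG_TO_NG = 1.0e3
NG_PER_MG = 1.0e6

UL_TO_L = 1.0e-6
ML_TO_L = 1.0e-3

PMOL_TO_MOL = 1.0e-12

#: molar mass of all-trans retinoic acid (C20H28O2), g/mol
ATRA_MOLAR_MASS = 300.44


def ng_to_pmol(mass_ng: float, molar_mass: float) -> float:
    """Convert nanograms to picomoles: ng / (g/mol) * 1000."""
    return mass_ng / molar_mass * 1.0e3


def pmol_to_ng(amount_pmol: float, molar_mass: float) -> float:
    return amount_pmol * molar_mass / 1.0e3


def per_day_to_per_hour(rate_per_day: float) -> float:
    return rate_per_day / HOURS_PER_DAY


def per_hour_to_per_day(rate_per_hour: float) -> float:
    return rate_per_hour * HOURS_PER_DAY


def molar(amount_pmol: float, volume_litres: float) -> float:
    """Concentration in mol/L from an amount in pmol and a volume in litres."""
    return amount_pmol * PMOL_TO_MOL / volume_litres
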