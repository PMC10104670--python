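"""Formulation and dose arithmetic for drug-loaded polymer microparticles.

Links the emulsion feed (polymer mass, drug feed mass, encapsulation
efficiency) to the drug weight fraction of the finished particles, and an
injected microparticle dose to absolute drug amounts and bolus
concentrations.  The default numbers describe all-trans retinoic acid
(ATRA) encapsulated in PLGA: a 2 mg : 100 mg drug:polymer feed at 62.4%
encapsulation efficiency gives particles of ≈1.2 wt% ATRA, and a 2 µg
intra-articular particle dose then carries ≈24 ng ≈ 80 pmol of drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import units


class ValidationError(ValueError):
    """Raised when a spec violates its physical invariants."""


@dataclass(frozen=True)
class FormulationSpec:
    """Emulsion feed composition and encapsulation efficiency.

    Parameters
    ----------
    polymer_mass:
        Polymer (PLGA) mass in the feed, mg.
    drug_feed_mass:
        Drug mass offered to the emulsion, mg.
    encapsulation_efficiency:
        Fraction of the drug feed that ends up inside particles, in [0, 1].
    drug_molar_mass:
        g/mol; defaults to ATRA (300.44).
    size_class_label:
        Free-text label of the particle size class, e.g. ``"6.5 um"``.
    """

    polymer_mass: float = 100.0
    drug_feed_mass: float = 2.0
    encapsulation_efficiency: float = 0.624
    drug_molar_mass: float = units.ATRA_MOLAR_MASS
    size_class_label: str = "6.5 um"

    def __post_init__(self) -> None:
        if self.polymer_mass < 0 or self.drug_feed_mass < 0:
            raise ValidationError("masses must be non-negative")
        if not 0.0 <= self.encapsulation_efficiency <= 1.0:
            raise ValidationError(
                "encapsulation_efficiency must lie in [0, 1], got "
                f"{self.encapsulation_efficiency!r}"
            )
        if self.drug_molar_mass <= 0:
            raise ValidationError("drug_molar_mass must be positive")
        if self.polymer_mass == 0 and self.drug_feed_mass == 0:
            raise ValidationError("formulation must contain some mass")


@dataclass(frozen=True)
class DoseSpec:
    """An injected microparticle dose and the fluid volume receiving it.

    ``synovial_volume`` defaults to the ≈20 µL synovial fluid volume of a
    mouse ankle joint.
    """

    mp_mass: float = 2.0           # µg of particles injected
    vehicle_volume: float = 20.0   # µL of injection vehicle
    synovial_volume: float = 20.0  # µL of synovial fluid

    def __post_init__(self) -> None:
        if self.mp_mass < 0:
            raise ValidationError("mp_mass must be non-negative")
        if self.vehicle_volume <= 0 or self.synovial_volume <= 0:
            raise ValidationError("volumes must be positive")


def loading_weight_fraction(spec: FormulationSpec) -> float:
    """Drug weight fraction of the finished particles.

    w = E·m_drug / (m_polymer + E·m_drug): the encapsulated drug mass over
    the total particle mass (polymer plus encapsulated drug).  For the
    default ATRA/PLGA feed this evaluates to ≈0.0123, i.e. ≈1.2 wt%.
    """
    encapsulated = spec.encapsulation_efficiency * spec.drug_feed_mass
    return encapsulated / (spec.polymer_mass + encapsulated)


def dose_to_drug_amount(
    dose: DoseSpec, loading: float, molar_mass: float = units.ATRA_MOLAR_MASS
) -> dict[str, float]:
    """Absolute drug content of an injected particle dose.

    Returns ``{"mass_ng": ..., "amount_pmol": ...}``.
    """
    if not 0.0 <= loading <= 1.0:
        raise ValidationError(f"loading must lie in [0, 1], got {loading!r}")
    mass_ng = dose.mp_mass * loading * units.UG_TO_NG
    return {
        "mass_ng": mass_ng,
        "amount_pmol": units.ng_to_pmol(mass_ng, molar_mass),
    }


def bolus_concentration(amount_pmol: float, volume_ul: float) -> float:
    """mol/L concentration of an amount dissolved instantly in a µL volume.

    Used for instantaneous-release sanity checks (e.g. the whole payload
    dumped into the synovial fluid at once).
    """
    if volume_ul <= 0:
        raise ValidationError("volume must be positive")
    if amount_pmol < 0:
        raise ValidationError("amount must be non-negative")
    return units.molar(amount_pmol, volume_ul * units.UL_TO_L)
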