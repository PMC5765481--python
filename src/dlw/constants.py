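"""Physical and model constants for doubly labelled water (DLW) analysis.

The DLW method derives CO2 production from the divergence of the ²H and ¹⁸O
elimination rates.  Everything that depends on the fractionation model — the
factors f1-f3, the alpha/beta/gamma constants of the physiological
re-parameterization, and the normalization ratios — lives here so that a
different fractionation convention can be swapped in from configuration
without touching the estimation code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

#: Molar mass of water, g/mol.
WATER_MOLAR_MASS = 18.02

#: Hydration fraction of fat-free mass (mass of water per mass of FFM).
HYDRATION_OF_FFM = 0.732

#: Quality-screen band for the natural dilution-space ratio N_H/N_O.
SPACE_RATIO_SCREEN = (1.015, 1.060)


def _gamma(pool_overestimate: float) -> float:
    # kg of body weight per mol of isotope space, through TBW and FFM
    # hydration; the mol -> kg bridge (18.02 / 1000) lives only here.
    return WATER_MOLAR_MASS / (2.0 * 1000.0 * HYDRATION_OF_FFM * pool_overestimate)


@dataclass(frozen=True)
class ModelConstants:
    """Constants of the DLW model, defaulting to the Schoeller fractionation model.

    Attributes
    ----------
    f1, f2, f3
        Fractionation factors for water vapour (²H, ¹⁸O) and CO2 (¹⁸O).
    alpha1, alpha2
        rCO2 = alpha1 * (k_O N_O - k_H N_H) + alpha2.
    beta1, beta2
        R_W = beta1 * k_H N_H + (1 - beta1) * k_O N_O + beta2.  The default
        (beta1 = 1, beta2 = 0) takes water turnover as the ²H efflux.
    gamma1, gamma2
        F = 1 - (gamma1 N_H + gamma2 N_O) / W; they convert the mean of the
        space-corrected pools to total body water and then to fat-free mass.
    rq
        Respiratory quotient assumed common to all subjects.
    weir_a, weir_b, weir_c
        TEE = weir_a * (weir_b / RQ + weir_c) * rCO2 (modified Weir equation).
    """

    f1: float = 0.941
    f2: float = 0.991
    f3: float = 1.037

    rq: float = 0.85
    weir_a: float = 22.4
    weir_b: float = 15.48
    weir_c: float = 5.55

    water_molar_mass: float = WATER_MOLAR_MASS

    # Coward equation constants
    coward_offset: float = 27.3
    coward_denom_coef: float = 1.1
    # Schoeller equation denominator coefficient
    schoeller_denom_coef: float = 2.1

    # Space-ratio normalization targets
    schoeller_ratio: float = 1.03
    iaea_h: float = 1.041
    iaea_o: float = 1.007

    # Physiological re-parameterization constants; defaults derived below.
    alpha1: float = field(default=0.0)
    alpha2: float = 0.0
    beta1: float = 1.0
    beta2: float = 0.0
    gamma1: float = field(default_factory=lambda: _gamma(1.041))
    gamma2: float = field(default_factory=lambda: _gamma(1.007))

    def __post_init__(self) -> None:
        if self.alpha1 == 0.0:
            object.__setattr__(self, "alpha1", 1.0 / self.schoeller_denominator)
        if not (self.f3 > 1.0 > self.f2 > self.f1 > 0.0):
            raise ValueError("fractionation factors must satisfy f3 > 1 > f2 > f1 > 0")
        if not (0.7 < self.rq < 1.0):
            raise ValueError(f"RQ {self.rq} outside the physiological range (0.7, 1.0)")

    @property
    def schoeller_denominator(self) -> float:
        return 2.0 * self.f3 + self.schoeller_denom_coef * (self.f2 - self.f1)

    @property
    def coward_denominator(self) -> float:
        return 2.0 * self.f3 + self.coward_denom_coef * (self.f2 - self.f1)

    @property
    def weir_factor(self) -> float:
        """kJ of energy expended per mol of CO2 produced at the assumed RQ."""
        return self.weir_a * (self.weir_b / self.rq + self.weir_c)

    @property
    def lambda_tee(self) -> float:
        """Slope of TEE on the isotope-flux difference (k_O N_O - k_H N_H)."""
        return self.weir_factor * self.alpha1

    @property
    def mu_tee(self) -> float:
        """Intercept of TEE on the isotope-flux difference."""
        return self.weir_factor * self.alpha2

    @property
    def iaea_ratio(self) -> float:
        return self.iaea_h / self.iaea_o

    @classmethod
    def schoeller(cls) -> "ModelConstants":
        """Constants with rCO2 on the Schoeller model (alpha2 = 0)."""
        return cls()

    @classmethod
    def coward(cls) -> "ModelConstants":
        """Constants with rCO2 on the Coward model (non-zero alpha2)."""
        base = cls()
        alpha1 = 1.0 / base.coward_denominator
        alpha2 = -base.coward_offset * (base.f2 - base.f1) / base.coward_denominator
        return replace(base, alpha1=alpha1, alpha2=alpha2)

    @classmethod
    def for_model(cls, model: Literal["schoeller", "coward"]) -> "ModelConstants":
        if model == "schoeller":
            return cls.schoeller()
        if model == "coward":
            return cls.coward()
        raise ValueError(f"unknown fractionation model {model!r}")


DEFAULT_CONSTANTS = ModelConstants()
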