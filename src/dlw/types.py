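"""Domain types for DLW records and parameters.

Two isotopes are followed: deuterium (²H) and oxygen-18 (¹⁸O).  All isotopic
enrichments are delta values in per-mil (‰) relative to VSMOW; times are days
post-dose; pool sizes are mol of body water; rate constants are per day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .constants import SPACE_RATIO_SCREEN

Isotope = Literal["2H", "18O"]

ISOTOPES: tuple[Isotope, Isotope] = ("2H", "18O")


class DomainError(ValueError):
    """A value violates a physical or model-domain constraint."""


@dataclass
class IsotopeCurve:
    """Post-dose enrichment time series for one isotope in one subject."""

    isotope: Isotope
    times: np.ndarray  # days post-dose, strictly increasing
    delta_values: np.ndarray  # ‰ vs VSMOW
    delta_b: float  # basal (pre-dose) enrichment, ‰ vs VSMOW

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta_values = np.asarray(self.delta_values, dtype=float)
        if self.isotope not in ISOTOPES:
            raise DomainError(f"unknown isotope {self.isotope!r}")
        if self.times.ndim != 1 or self.times.shape != self.delta_values.shape:
            raise DomainError("times and delta_values must be matching 1-D arrays")
        if self.times.size and self.times.min() < 0:
            raise DomainError("post-dose times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")

    @property
    def excess(self) -> np.ndarray:
        """Enrichment above basal, ‰."""
        return self.delta_values - self.delta_b


@dataclass
class DosePrep:
    """Dose masses and the dose-dilution measurement for one isotope.

    The administered dose is ``D`` grams; an aliquot of ``d`` grams was
    diluted into ``T`` grams of tap water of enrichment ``delta_T`` to give
    the measured diluted-dose enrichment ``delta_dd``.
    """

    D: float  # g given to the subject
    d: float  # g of dose aliquot diluted
    T: float  # g of dilution water
    delta_dd: float  # ‰, diluted dose
    delta_T: float  # ‰, dilution water

    def __post_init__(self) -> None:
        if min(self.D, self.d, self.T) <= 0:
            raise DomainError("dose masses D, d, T must all be positive")
        if self.delta_dd <= self.delta_T:
            raise DomainError("diluted dose must be enriched above the dilution water")


@dataclass
class SubjectRecord:
    """One subject's anthropometry, dosing and two-isotope enrichment data."""

    id: str
    sex: Literal["F", "M"]
    weight: float  # kg
    doses: dict[Isotope, DosePrep]
    curves: dict[Isotope, IsotopeCurve]

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise DomainError("body weight must be positive")
        for iso in ISOTOPES:
            if iso not in self.doses or iso not in self.curves:
                raise DomainError(f"subject {self.id}: missing isotope {iso}")
            if self.curves[iso].isotope != iso:
                raise DomainError(f"subject {self.id}: curve labelled {self.curves[iso].isotope}, keyed {iso}")


@dataclass(frozen=True)
class KineticParams:
    """Per-isotope pool sizes (mol) and elimination rate constants (day⁻¹)."""

    N_H: float
    N_O: float
    k_H: float
    k_O: float

    def __post_init__(self) -> None:
        if min(self.N_H, self.N_O, self.k_H, self.k_O) <= 0:
            raise DomainError("pool sizes and rate constants must be positive")

    @property
    def space_ratio(self) -> float:
        return self.N_H / self.N_O

    @property
    def physiologically_valid(self) -> bool:
        """¹⁸O must turn over faster than ²H (CO2 adds to the ¹⁸O efflux)."""
        return self.k_O > self.k_H


@dataclass(frozen=True)
class PhysioParams:
    """The four physiological parameters of the re-parameterized DLW model.

    rCO2: CO2 production, mol/day; S: dilution-space ratio N_H/N_O;
    R_W: water turnover, mol/day; F: body-fat fraction.
    """

    rCO2: float
    S: float
    R_W: float
    F: float

    def __post_init__(self) -> None:
        if not (0.0 < self.rCO2 < 100.0):
            raise DomainError(f"rCO2 {self.rCO2} outside (0, 100) mol/day")
        if not (0.0 < self.R_W < 1000.0):
            raise DomainError(f"R_W {self.R_W} outside (0, 1000) mol/day")
        if not (0.0 < self.F < 1.0):
            raise DomainError(f"body-fat fraction {self.F} outside (0, 1)")
        if self.S <= 0:
            raise DomainError("space ratio must be positive")


def check_space_ratio(S: float, subject_id: str = "") -> bool:
    """Quality screen on the natural space ratio; warns rather than rejects.

    Returns True when S lies in the conventional acceptability band.
    """
    lo, hi = SPACE_RATIO_SCREEN
    ok = lo <= S <= hi
    if not ok:
        label = f" for subject {subject_id}" if subject_id else ""
        warnings.warn(
            f"space ratio {S:.4f}{label} outside the screen band [{lo}, {hi}]",
            stacklevel=2,
        )
    return ok
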