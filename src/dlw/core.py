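"""Forward kinetic model, parameter transformations and energy conversion.

The DLW model assumes first-order elimination of both labels, so the
enrichment of isotope *i* follows

    delta_i(t) = A_i * exp(-k_i t) + delta_b,i

where the intercept above basal is fixed by the dose preparation,

    A_i = D T (delta_dd - delta_T) / (18.02 N_i d).

The two-isotope kinetics (N_H, N_O, k_H, k_O) are equivalent to four
physiological parameters: the CO2 production rCO2, the dilution-space ratio
S = N_H / N_O, the water turnover R_W, and the body-fat fraction F.  Both
directions of that transformation are implemented here, together with the
Coward and Schoeller rCO2 equations, the dilution-space normalizations, the
modified Weir equation, and the closed-form effect of normalization on TEE.
"""

from __future__ import annotations

import numpy as np

from .constants import DEFAULT_CONSTANTS, ModelConstants
from .types import DomainError, DosePrep, KineticParams, PhysioParams


def dose_amplitude(dose: DosePrep, N: float, c: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Intercept above basal (‰) implied by a dose and a pool size N (mol)."""
    if N <= 0:
        raise DomainError("pool size N must be positive")
    return dose.D * dose.T * (dose.delta_dd - dose.delta_T) / (c.water_molar_mass * N * dose.d)


def pool_from_amplitude(dose: DosePrep, amplitude: float, c: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Invert :func:`dose_amplitude`: pool size N (mol) from the ‰ intercept."""
    if amplitude <= 0:
        raise DomainError("intercept above basal must be positive")
    return dose.D * dose.T * (dose.delta_dd - dose.delta_T) / (c.water_molar_mass * amplitude * dose.d)


def enrichment_at(
    t,
    dose: DosePrep,
    N: float,
    k: float,
    delta_b: float,
    c: ModelConstants = DEFAULT_CONSTANTS,
):
    """Predicted enrichment delta(t) in ‰ at time(s) t days post-dose."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be non-negative")
    if N <= 0:
        raise DomainError("pool size N must be positive")
    if k < 0:
        raise DomainError("rate constant k must be non-negative")
    if dose.D == 0:  # unreachable through DosePrep, kept for raw calls
        return np.broadcast_to(delta_b, t.shape).copy()
    out = dose_amplitude(dose, N, c) * np.exp(-k * t) + delta_b
    return out if out.ndim else float(out)


def physio_from_kinetic(kin: KineticParams, W: float, c: ModelConstants = DEFAULT_CONSTANTS) -> PhysioParams:
    """Map kinetics to (rCO2, S, R_W, F) for a subject of weight W kg."""
    if W <= 0:
        raise DomainError("body weight must be positive")
    flux_H = kin.k_H * kin.N_H
    flux_O = kin.k_O * kin.N_O
    return PhysioParams(
        rCO2=c.alpha1 * (flux_O - flux_H) + c.alpha2,
        S=kin.N_H / kin.N_O,
        R_W=c.beta1 * flux_H + (1.0 - c.beta1) * flux_O + c.beta2,
        F=1.0 - (c.gamma1 * kin.N_H + c.gamma2 * kin.N_O) / W,
    )


def kinetic_from_physio(phys: PhysioParams, W: float, c: ModelConstants = DEFAULT_CONSTANTS) -> KineticParams:
    """Invert :func:`physio_from_kinetic`; raises DomainError off the physical manifold."""
    if W <= 0:
        raise DomainError("body weight must be positive")
    denom = c.gamma1 * phys.S + c.gamma2
    if denom <= 0:
        raise DomainError("gamma1*S + gamma2 must be positive")
    lean = W * (1.0 - phys.F)
    N_O = lean / denom
    N_H = phys.S * N_O
    # Solve beta1*x + (1-beta1)*y = R_W - beta2 and y - x = (rCO2 - alpha2)/alpha1
    # for the two effluxes x = k_H N_H, y = k_O N_O.
    flux_diff = (phys.rCO2 - c.alpha2) / c.alpha1
    flux_H = (phys.R_W - c.beta2) - (1.0 - c.beta1) * flux_diff
    flux_O = flux_H + flux_diff
    if flux_H <= 0 or flux_O <= 0:
        raise DomainError("parameters imply a non-positive isotope efflux")
    return KineticParams(N_H=N_H, N_O=N_O, k_H=flux_H / N_H, k_O=flux_O / N_O)


def rco2_coward(kin: KineticParams, c: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """CO2 production (mol/day) by the Coward equation, for natural (non-normalized) spaces."""
    num = kin.k_O * kin.N_O - kin.k_H * kin.N_H - c.coward_offset * (c.f2 - c.f1)
    return num / c.coward_denominator


def rco2_schoeller(kin: KineticParams, c: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """CO2 production (mol/day) by the Schoeller equation, for normalized spaces."""
    num = kin.k_O * kin.N_O - kin.k_H * kin.N_H
    return num / c.schoeller_denominator


def weir_tee(rCO2: float, RQ: float | None = None, c: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Total energy expenditure (kJ/day) from CO2 production by the modified Weir equation.

    TEE = 22.4 (15.48 / RQ + 5.55) rCO2; at RQ = 0.85 the bracket evaluates to
    a proportionality constant of ~532 kJ per mol CO2.
    """
    if RQ is None:
        RQ = c.rq
    if not (0.7 < RQ < 1.0):
        raise DomainError(f"RQ {RQ} outside the physiological range (0.7, 1.0)")
    if rCO2 < 0:
        raise DomainError("rCO2 must be non-negative")
    return c.weir_a * (c.weir_b / RQ + c.weir_c) * rCO2


def normalize_spaces_schoeller(
    N_H_obs: float, N_O_obs: float, c: ModelConstants = DEFAULT_CONSTANTS
) -> tuple[float, float]:
    """Weight the observed spaces to a fixed ²H/¹⁸O ratio of 1.03."""
    if N_H_obs <= 0 or N_O_obs <= 0:
        raise DomainError("observed spaces must be positive")
    r = c.schoeller_ratio
    N_H = 0.5 * (N_H_obs + r * N_O_obs)
    N_O = 0.5 * (N_H_obs / r + N_O_obs)
    return N_H, N_O


def normalize_spaces_iaea(
    N_H_obs: float, N_O_obs: float, c: ModelConstants = DEFAULT_CONSTANTS
) -> tuple[float, float]:
    """IAEA normalization: both spaces scaled from the mean body-water estimate.

    Fixes the output ratio at 1.041 / 1.007 = 1.034 (3 d.p.).
    """
    if N_H_obs <= 0 or N_O_obs <= 0:
        raise DomainError("observed spaces must be positive")
    mean_bw = 0.5 * (N_H_obs / c.iaea_h + N_O_obs / c.iaea_o)
    return c.iaea_h * mean_bw, c.iaea_o * mean_bw


def normalized_oxygen_space(N_O: float, S: float, S_target: float) -> float:
    """Oxygen space after normalizing a subject with natural ratio S to S_target."""
    return 0.5 * (S / S_target + 1.0) * N_O


def tee_from_fluxes(kin: KineticParams, c: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """TEE as the linear function lambda (k_O N_O - k_H N_H) + mu of the flux difference."""
    return c.lambda_tee * (kin.k_O * kin.N_O - kin.k_H * kin.N_H) + c.mu_tee


def normalization_tee_shift(
    kin: KineticParams, S_target: float, c: ModelConstants = DEFAULT_CONSTANTS
) -> float:
    """Closed-form change in TEE (kJ/day) caused by normalizing the space ratio.

    TEE' - TEE = lambda (S/S' - 1) [(k_O + S' k_H)/2] N_O, where S is the
    natural ratio and S' the normalization target.  Identically equal to
    recomputing TEE with the normalized oxygen space.
    """
    if S_target <= 0:
        raise DomainError("normalization target must be positive")
    S = kin.space_ratio
    return (
        c.lambda_tee
        * (S / S_target - 1.0)
        * 0.5
        * (kin.k_O + S_target * kin.k_H)
        * kin.N_O
    )
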