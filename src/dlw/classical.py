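"""Classical (non-Bayesian) estimation of DLW kinetics and TEE.

Three flavours of per-isotope curve fitting are provided, differing only in
their implied error structure:

* ``logarithmic`` — ordinary least squares on ln(delta - delta_b) vs t, the
  traditional slope-intercept analysis; appropriate when the ‰ error is
  proportional to the excess enrichment.
* ``poisson`` — weighted least squares on the log scale with weights
  proportional to the excess enrichment, the intermediate error model.
* ``exponential`` — nonlinear least squares on the untransformed curve;
  appropriate for constant (instrumental) ‰ error.

All three agree exactly on noise-free data.  TEE follows by composing the
fitted kinetics with the rCO2 equations and the Weir conversion; natural
spaces go through the Coward equation and normalized spaces through the
Schoeller equation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

from . import core
from .constants import DEFAULT_CONSTANTS, ModelConstants
from .types import (
    DosePrep,
    IsotopeCurve,
    KineticParams,
    SubjectRecord,
    check_space_ratio,
)

logger = logging.getLogger(__name__)

FIT_METHODS = ("logarithmic", "poisson", "exponential")
NORMALIZATIONS = ("none", "schoeller", "iaea")


class FitError(RuntimeError):
    """A curve fit could not be performed or did not converge."""


@dataclass
class FitResult:
    """Result of fitting one isotope's elimination curve."""

    method: str
    amplitude: float  # intercept above basal at t=0, ‰
    k: float  # day⁻¹
    N: float  # mol, from the dose equation at t=0
    se_k: float
    se_N: float
    cov_Nk: np.ndarray  # 2x2 covariance of (N, k)
    residuals: np.ndarray  # observed - fitted, ‰, at the fitted timepoints
    n_dropped: int = 0

    @property
    def rms_residual(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2)))


def _prepare(curve: IsotopeCurve) -> tuple[np.ndarray, np.ndarray, int]:
    """Average duplicate timepoints and drop points at or below basal."""
    t, y = curve.times, curve.delta_values
    ut, inv = np.unique(t, return_inverse=True)
    if ut.size != t.size:
        y = np.bincount(inv, weights=y) / np.bincount(inv)
        t = ut
    excess = y - curve.delta_b
    bad = excess <= 0
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning(
            "%s curve: dropping %d point(s) at or below basal (t=%s)",
            curve.isotope, n_dropped, t[bad],
        )
    t, excess = t[~bad], excess[~bad]
    if t.size < 2:
        raise FitError("fewer than 2 usable points above basal")
    return t, excess, n_dropped


def _from_log_fit(res, dose: DosePrep, t, excess, delta_b, method, n_dropped, c) -> FitResult:
    b0, b1 = res.params
    k = -b1
    if k <= 0:
        raise FitError("non-positive elimination rate from log-linear fit")
    A = float(np.exp(b0))
    N = core.pool_from_amplitude(dose, A, c)
    # delta method: N = C exp(-b0) so dN/db0 = -N; k = -b1.
    # A saturated (two-point) fit has no residual dof: V is NaN and so are the SEs.
    J = np.array([[-N, 0.0], [0.0, -1.0]])
    with np.errstate(divide="ignore", invalid="ignore"):
        V = np.asarray(res.cov_params())
        cov = J @ V @ J.T
    fitted = A * np.exp(-k * t)
    return FitResult(
        method=method, amplitude=A, k=k, N=N,
        se_k=float(np.sqrt(cov[1, 1])), se_N=float(np.sqrt(cov[0, 0])),
        cov_Nk=cov, residuals=excess - fitted, n_dropped=n_dropped,
    )


def fit_logarithmic(
    curve: IsotopeCurve, dose: DosePrep, c: ModelConstants = DEFAULT_CONSTANTS
) -> FitResult:
    """Slope-intercept fit: OLS on the semi-log transformed disappearance curve."""
    t, excess, n_dropped = _prepare(curve)
    X = sm.add_constant(t)
    res = sm.OLS(np.log(excess), X).fit()
    return _from_log_fit(res, dose, t, excess, curve.delta_b, "logarithmic", n_dropped, c)


def fit_poisson(
    curve: IsotopeCurve, dose: DosePrep, c: ModelConstants = DEFAULT_CONSTANTS
) -> FitResult:
    """Log-scale fit weighted by the excess enrichment (Poisson-like variance)."""
    t, excess, n_dropped = _prepare(curve)
    X = sm.add_constant(t)
    res = sm.WLS(np.log(excess), X, weights=excess).fit()
    return _from_log_fit(res, dose, t, excess, curve.delta_b, "poisson", n_dropped, c)


def fit_exponential(
    curve: IsotopeCurve, dose: DosePrep, c: ModelConstants = DEFAULT_CONSTANTS
) -> FitResult:
    """Nonlinear least squares on the untransformed curve, seeded from the log fit."""
    init = fit_logarithmic(curve, dose, c)
    t, excess, n_dropped = _prepare(curve)

    def model(tt, A, k):
        return A * np.exp(-k * tt)

    try:
        popt, pcov = curve_fit(
            model, t, excess, p0=[init.amplitude, init.k],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    A, k = popt
    if k <= 0 or A <= 0:
        raise FitError("exponential fit hit the parameter boundary")
    N = core.pool_from_amplitude(dose, A, c)
    # transform cov(A, k) -> cov(N, k); dN/dA = -N/A
    J = np.array([[-N / A, 0.0], [0.0, 1.0]])
    cov = J @ pcov @ J.T
    fitted = model(t, A, k)
    return FitResult(
        method="exponential", amplitude=float(A), k=float(k), N=N,
        se_k=float(np.sqrt(cov[1, 1])), se_N=float(np.sqrt(cov[0, 0])),
        cov_Nk=cov, residuals=excess - fitted, n_dropped=n_dropped,
    )


_FITTERS = {
    "logarithmic": fit_logarithmic,
    "poisson": fit_poisson,
    "exponential": fit_exponential,
}


def fit_curve(curve, dose, method: str = "exponential", c: ModelConstants = DEFAULT_CONSTANTS):
    try:
        fitter = _FITTERS[method]
    except KeyError:
        raise ValueError(f"unknown fit method {method!r}; choose from {FIT_METHODS}") from None
    return fitter(curve, dose, c)


@dataclass
class ClassicalTEE:
    """Per-subject classical TEE estimate with diagnostics."""

    subject_id: str
    method: str
    normalization: str
    kin: KineticParams  # fitted (natural) kinetics
    S_natural: float
    rCO2: float
    TEE: float  # kJ/day
    cv: float | None = None  # approximate CV of TEE from the fit covariances
    flags: list[str] = field(default_factory=list)


def classical_tee(
    subject: SubjectRecord,
    method: str = "exponential",
    normalization: str = "none",
    c: ModelConstants = DEFAULT_CONSTANTS,
) -> ClassicalTEE:
    """Fit both isotopes and derive TEE, optionally normalizing the spaces.

    The natural path evaluates the Coward equation on the fitted kinetics;
    the normalized paths first correct the pool sizes to the fixed ratio
    (rate constants untouched) and then evaluate the Schoeller equation.
    """
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"unknown normalization {normalization!r}; choose from {NORMALIZATIONS}")
    fit_H = fit_curve(subject.curves["2H"], subject.doses["2H"], method, c)
    fit_O = fit_curve(subject.curves["18O"], subject.doses["18O"], method, c)
    kin = KineticParams(N_H=fit_H.N, N_O=fit_O.N, k_H=fit_H.k, k_O=fit_O.k)
    S_nat = kin.space_ratio

    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if not check_space_ratio(S_nat, subject.id):
            flags.append("space_ratio_outside_screen")
    if not kin.physiologically_valid:
        flags.append("invalid_kO_le_kH")

    if normalization == "none":
        rco2 = core.rco2_coward(kin, c)
    else:
        normalizer = {
            "schoeller": core.normalize_spaces_schoeller,
            "iaea": core.normalize_spaces_iaea,
        }[normalization]
        N_H, N_O = normalizer(kin.N_H, kin.N_O, c)
        rco2 = core.rco2_schoeller(
            KineticParams(N_H=N_H, N_O=N_O, k_H=kin.k_H, k_O=kin.k_O), c
        )
    if rco2 <= 0:
        flags.append("nonpositive_rco2")
        tee = 0.0
    else:
        tee = core.weir_tee(rco2, c.rq, c)
    try:
        cv = propagate_error(fit_H, fit_O, c)
    except FitError:
        cv = None
    return ClassicalTEE(
        subject_id=subject.id, method=method, normalization=normalization,
        kin=kin, S_natural=S_nat, rCO2=rco2, TEE=tee, cv=cv, flags=flags,
    )


def propagate_error(fit_H: FitResult, fit_O: FitResult, c: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """First-order (delta-method) CV of rCO2 — and hence of TEE — from the fits.

    The two isotope fits are treated as independent; within an isotope the
    full (N, k) covariance from the fit is used.  rCO2 is linear in the flux
    difference, so its CV carries over to TEE unchanged.
    """
    for f in (fit_H, fit_O):
        if not np.all(np.isfinite(f.cov_Nk)):
            raise FitError("fit does not carry finite standard errors")
    # rCO2 = alpha1 (k_O N_O - k_H N_H) + alpha2
    gH = np.array([-fit_H.k, -fit_H.N])  # d/d(N_H, k_H)
    gO = np.array([fit_O.k, fit_O.N])
    var = c.alpha1**2 * (gH @ fit_H.cov_Nk @ gH + gO @ fit_O.cov_Nk @ gO)
    rco2 = c.alpha1 * (fit_O.k * fit_O.N - fit_H.k * fit_H.N) + c.alpha2
    if rco2 <= 0:
        raise FitError("non-positive rCO2; CV undefined")
    return float(np.sqrt(var) / rco2)


@dataclass
class ComparisonStats:
    """Bland-Altman agreement statistics between two TEE series (b - a)."""

    n: int
    mean_difference: float
    median_difference: float
    sd_difference: float
    lower_loa: float  # mean - 1.96 sd
    upper_loa: float  # mean + 1.96 sd
    slope: float  # of difference on pair mean

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_difference": self.mean_difference,
            "median_difference": self.median_difference,
            "sd_difference": self.sd_difference,
            "lower_loa": self.lower_loa,
            "upper_loa": self.upper_loa,
            "slope": self.slope,
        }


def bland_altman(tee_a, tee_b) -> ComparisonStats:
    """Limits of agreement and difference-vs-mean slope for paired series."""
    a = np.asarray(tee_a, dtype=float)
    b = np.asarray(tee_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired series must be 1-D and equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs for limits of agreement")
    diff = b - a
    mean_pair = 0.5 * (a + b)
    m = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if np.ptp(mean_pair) > 0:
        slope = float(np.polyfit(mean_pair, diff, 1)[0])
    else:
        slope = 0.0
    return ComparisonStats(
        n=a.size, mean_difference=m, median_difference=float(np.median(diff)),
        sd_difference=sd, lower_loa=m - 1.96 * sd, upper_loa=m + 1.96 * sd,
        slope=slope,
    )
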