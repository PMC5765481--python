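"""Bayesian estimation of DLW physiological parameters by MCMC.

The model is parameterized directly in the four physiological quantities
(rCO2, S, R_W, F).  Sampled values are mapped to kinetics (N_H, N_O, k_H,
k_O), the forward first-order model predicts every observed enrichment, and
independent Gaussian measurement error with isotope-specific standard
deviations (2 ‰ for ²H, 0.5 ‰ for ¹⁸O by default) closes the likelihood.

Two model variants are provided:

* independent — each subject analysed alone under vague priors for rCO2,
  R_W and F and an informative Normal(1.035, 0.01) prior for the space
  ratio S;
* hierarchical — individual parameters drawn from population (hyper)
  distributions, one stratum at a time (the cohort analyses split by sex);
  Gamma(0.01, 0.01) precision hyperpriors for rCO2, R_W and F, and a
  Uniform(1, 100000) precision for S.

The sampler is component-wise random-walk Metropolis with proposal scales
adapted during burn-in only, so the post-burn-in chain satisfies detailed
balance.  Hypermeans and precisions have conjugate (or truncated-conjugate)
full conditionals and are Gibbs-updated.  TEE is a derived quantity,
proportional to rCO2 draw by draw through the Weir factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc, gammaincinv, ndtr, ndtri

from .classical import classical_tee
from .constants import DEFAULT_CONSTANTS, ModelConstants
from .core import physio_from_kinetic
from .types import PhysioParams, SubjectRecord

PARAM_NAMES = ("rCO2", "S", "R_W", "F")
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the independent per-subject model."""

    rco2_bounds: tuple[float, float] = (0.0, 100.0)  # mol/day, uniform
    rw_bounds: tuple[float, float] = (0.0, 1000.0)  # mol/day, uniform
    f_bounds: tuple[float, float] = (0.0, 1.0)  # uniform
    s_mean: float = 1.035
    s_sd: float = 0.01  # precision 10000
    sigma_2h: float = 2.0  # ‰ measurement sd
    sigma_18o: float = 0.5  # ‰ measurement sd

    def __post_init__(self) -> None:
        if self.s_sd <= 0 or self.sigma_2h <= 0 or self.sigma_18o <= 0:
            raise ValueError("standard deviations must be positive")

    def bounds(self, name: str) -> tuple[float, float]:
        return {
            "rCO2": self.rco2_bounds,
            "S": (0.0, np.inf),
            "R_W": self.rw_bounds,
            "F": self.f_bounds,
        }[name]


@dataclass(frozen=True)
class HierPriorSpec:
    """Hyperpriors of the hierarchical (population) model.

    Hypermeans adopt the vague per-subject priors of the independent model
    (and the informative normal for S).  Between-subject precisions are
    Gamma(0.01, 0.01) for rCO2, R_W and F, and Uniform(1, 100000) for S.
    """

    base: PriorSpec = field(default_factory=PriorSpec)
    tau_shape: float = 0.01
    tau_rate: float = 0.01
    tau_s_bounds: tuple[float, float] = (1.0, 100000.0)


@dataclass(frozen=True)
class MCMCConfig:
    """Markov-chain configuration; defaults follow the reference run length."""

    iterations: int = 50_000
    burn_in: int = 4_000
    thin: int = 1
    chains: int = 2
    seed: int = 0
    proposal_scales: tuple[float, float, float, float] = (1.0, 0.005, 5.0, 0.02)
    adapt_interval: int = 50
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn-in must be non-negative and below the iteration count")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be at least 1")

    @property
    def n_keep(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorResult:
    """Draws and summaries from one MCMC run.

    ``draws`` maps parameter name to an array of shape (chains, draws) for
    scalar parameters or (chains, draws, subjects) for per-subject
    parameters of a cohort run.
    """

    draws: dict[str, np.ndarray]
    config: MCMCConfig
    subject_ids: list[str] | None = None
    diagnostics: dict = field(default_factory=dict)

    def stacked(self, name: str) -> np.ndarray:
        """All post-burn-in draws of a parameter, chains concatenated."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])


class _SubjectData:
    """Pre-extracted arrays for fast likelihood evaluation."""

    __slots__ = ("id", "W", "t_H", "y_H", "amp_H", "db_H", "t_O", "y_O", "amp_O", "db_O")

    def __init__(self, subject: SubjectRecord, c: ModelConstants):
        self.id = subject.id
        self.W = subject.weight
        for iso, suffix in (("2H", "H"), ("18O", "O")):
            curve, dose = subject.curves[iso], subject.doses[iso]
            setattr(self, f"t_{suffix}", curve.times)
            setattr(self, f"y_{suffix}", curve.delta_values)
            # amplitude * (1/N) is the t=0 excess enrichment
            amp = dose.D * dose.T * (dose.delta_dd - dose.delta_T) / (c.water_molar_mass * dose.d)
            setattr(self, f"amp_{suffix}", amp)
            setattr(self, f"db_{suffix}", curve.delta_b)


def _kinetics(theta: np.ndarray, W: float, c: ModelConstants):
    """theta = (rCO2, S, R_W, F) -> (N_H, N_O, k_H, k_O) or None if invalid."""
    rco2, S, RW, F = theta
    denom = c.gamma1 * S + c.gamma2
    if denom <= 0:
        return None
    N_O = W * (1.0 - F) / denom
    if N_O <= 0:
        return None
    N_H = S * N_O
    flux_diff = (rco2 - c.alpha2) / c.alpha1
    flux_H = (RW - c.beta2) - (1.0 - c.beta1) * flux_diff
    flux_O = flux_H + flux_diff
    if flux_H <= 0 or flux_O <= 0:
        return None
    return N_H, N_O, flux_H / N_H, flux_O / N_O


def _loglik(data: _SubjectData, theta: np.ndarray, priors: PriorSpec, c: ModelConstants) -> float:
    """Gaussian log likelihood up to the (constant) normalization terms."""
    kin = _kinetics(theta, data.W, c)
    if kin is None:
        return -np.inf
    N_H, N_O, k_H, k_O = kin
    r_H = data.y_H - (data.amp_H / N_H) * np.exp(-k_H * data.t_H) - data.db_H
    r_O = data.y_O - (data.amp_O / N_O) * np.exp(-k_O * data.t_O) - data.db_O
    return -0.5 * (
        float(r_H @ r_H) / priors.sigma_2h**2 + float(r_O @ r_O) / priors.sigma_18o**2
    )


def _in_support(theta: np.ndarray, priors: PriorSpec) -> bool:
    rco2, S, RW, F = theta
    return (
        priors.rco2_bounds[0] < rco2 < priors.rco2_bounds[1]
        and priors.rw_bounds[0] < RW < priors.rw_bounds[1]
        and priors.f_bounds[0] < F < priors.f_bounds[1]
        and S > 0
    )


def _logprior(theta: np.ndarray, priors: PriorSpec) -> float:
    if not _in_support(theta, priors):
        return -np.inf
    z = (theta[1] - priors.s_mean) / priors.s_sd
    return -0.5 * z * z


def log_likelihood(
    subject: SubjectRecord,
    phys: PhysioParams,
    priors: PriorSpec | None = None,
    c: ModelConstants = DEFAULT_CONSTANTS,
) -> float:
    """Full Gaussian log likelihood of one subject's data at ``phys``.

    Returns -inf (rather than raising) when the parameters imply an invalid
    kinetic state, so samplers can simply reject such proposals.
    """
    priors = priors or PriorSpec()
    data = _SubjectData(subject, c)
    theta = np.array([phys.rCO2, phys.S, phys.R_W, phys.F])
    if not _in_support(theta, priors):
        return -np.inf
    core_term = _loglik(data, theta, priors, c)
    if not np.isfinite(core_term):
        return -np.inf
    n_H, n_O = data.y_H.size, data.y_O.size
    const = -0.5 * (n_H + n_O) * _LOG_2PI - n_H * math.log(priors.sigma_2h) - n_O * math.log(
        priors.sigma_18o
    )
    return core_term + const


def _default_init(data: _SubjectData, priors: PriorSpec) -> np.ndarray:
    return np.array([20.0, priors.s_mean, 150.0 * data.W / 70.0, 0.30])


def _initial_theta(subject: SubjectRecord, priors: PriorSpec, c: ModelConstants) -> np.ndarray:
    """Start from the classical exponential fit when it is usable."""
    data = _SubjectData(subject, c)
    try:
        fit = classical_tee(subject, method="exponential", normalization="none", c=c)
        phys = physio_from_kinetic(fit.kin, subject.weight, c)
        theta = np.array([phys.rCO2, phys.S, phys.R_W, phys.F])
    except Exception:
        return _default_init(data, priors)
    if _in_support(theta, priors) and np.isfinite(_loglik(data, theta, priors, c)):
        return theta
    return _default_init(data, priors)


def _chain_rng(seed: int, chain: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(chain,)))


def _check_acceptance(rates: dict, context: str) -> None:
    for name, r in rates.items():
        if not (0.05 <= r <= 0.95):
            warnings.warn(
                f"{context}: acceptance rate {r:.2f} for {name} outside [0.05, 0.95]",
                stacklevel=3,
            )


def sample_independent(
    subject: SubjectRecord,
    priors: PriorSpec | None = None,
    cfg: MCMCConfig | None = None,
    c: ModelConstants = DEFAULT_CONSTANTS,
    prior_only: bool = False,
    fixed: dict[str, float] | None = None,
) -> PosteriorResult:
    """Posterior sampling for a single subject under the independent model.

    Parameters
    ----------
    prior_only
        Switch the likelihood off to sample from the prior alone (a sampler
        check; the S draws must then recover Normal(1.035, 0.01)).
    fixed
        Map of parameter names to values held constant (not sampled), e.g.
        ``{"rCO2": 25.0, "R_W": 200.0, "F": 0.3}`` to explore S alone.
    """
    priors = priors or PriorSpec()
    cfg = cfg or MCMCConfig()
    data = _SubjectData(subject, c)
    fixed = fixed or {}
    free = [j for j, name in enumerate(PARAM_NAMES) if name not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")

    def logpost(theta: np.ndarray) -> float:
        lp = _logprior(theta, priors)
        if not np.isfinite(lp):
            return -np.inf
        if prior_only:
            return lp
        return lp + _loglik(data, theta, priors, c)

    theta0 = _initial_theta(subject, priors, c)
    for name, value in fixed.items():
        theta0[PARAM_NAMES.index(name)] = value
    if prior_only:
        theta0 = _default_init(data, priors)
        for name, value in fixed.items():
            theta0[PARAM_NAMES.index(name)] = value

    out = {name: np.empty((cfg.chains, cfg.n_keep)) for name in PARAM_NAMES}
    accept = np.zeros((cfg.chains, 4))
    for chain in range(cfg.chains):
        rng = _chain_rng(cfg.seed, chain)
        theta = theta0.copy()
        lp = logpost(theta)
        if not np.isfinite(lp):  # fall back to prior draws for a valid start
            for _ in range(1000):
                theta = np.array([
                    rng.uniform(*priors.rco2_bounds),
                    rng.normal(priors.s_mean, priors.s_sd),
                    rng.uniform(*priors.rw_bounds),
                    rng.uniform(*priors.f_bounds),
                ])
                for name, value in fixed.items():
                    theta[PARAM_NAMES.index(name)] = value
                lp = logpost(theta)
                if np.isfinite(lp):
                    break
            else:
                raise RuntimeError(f"no valid starting point found for subject {subject.id}")
        scales = np.array(cfg.proposal_scales, dtype=float)
        window = np.zeros(4)
        kept = 0
        for it in range(cfg.iterations):
            for j in free:
                prop = theta.copy()
                prop[j] += scales[j] * rng.standard_normal()
                lpp = logpost(prop)
                if lpp - lp > math.log(rng.uniform()):
                    theta, lp = prop, lpp
                    window[j] += 1
                    if it >= cfg.burn_in:
                        accept[chain, j] += 1
            if it < cfg.burn_in and (it + 1) % cfg.adapt_interval == 0:
                rates = window / cfg.adapt_interval
                scales[free] *= np.exp(rates[free] - cfg.target_accept)
                window[:] = 0.0
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                for jname, val in zip(PARAM_NAMES, theta):
                    out[jname][chain, kept] = val
                kept += 1

    out["TEE"] = c.weir_factor * out["rCO2"]
    n_post = cfg.iterations - cfg.burn_in
    rates = {
        name: float(accept[:, j].sum()) / (cfg.chains * n_post)
        for j, name in enumerate(PARAM_NAMES)
        if j in free
    }
    _check_acceptance(rates, f"subject {subject.id}")
    diagnostics = {"acceptance_rates": rates}
    diagnostics.update(convergence_diagnostics(out))
    return PosteriorResult(draws=out, config=cfg, diagnostics=diagnostics)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    if b - a < 1e-14:  # numerically degenerate window: clip
        return min(max(mean, lo), hi)
    return mean + sd * float(ndtri(rng.uniform(a, b)))


def _trunc_gamma(rng: np.random.Generator, shape: float, rate: float, lo: float, hi: float) -> float:
    a, b = gammainc(shape, rate * lo), gammainc(shape, rate * hi)
    if b - a < 1e-14:
        return min(max(shape / rate, lo), hi)
    return float(gammaincinv(shape, rng.uniform(a, b))) / rate


def sample_hierarchical(
    subjects: list[SubjectRecord],
    priors: HierPriorSpec | None = None,
    cfg: MCMCConfig | None = None,
    c: ModelConstants = DEFAULT_CONSTANTS,
) -> PosteriorResult:
    """Joint posterior sampling for one cohort stratum under the hierarchical model.

    Individual parameters are Metropolis-updated against their conditional
    normal population prior; hypermeans and precisions are Gibbs-updated
    from their (truncated-)conjugate full conditionals.  Callers analysing a
    mixed cohort split it by sex first.
    """
    if len(subjects) < 3:
        raise ValueError("hierarchical analysis needs at least 3 subjects")
    priors = priors or HierPriorSpec()
    base = priors.base
    cfg = cfg or MCMCConfig()
    datas = [_SubjectData(s, c) for s in subjects]
    n = len(subjects)

    hyper_bounds = {
        "rCO2": base.rco2_bounds,
        "R_W": base.rw_bounds,
        "F": base.f_bounds,
    }

    theta_init = np.array([_initial_theta(s, base, c) for s in subjects])  # (n, 4)

    out = {name: np.empty((cfg.chains, cfg.n_keep, n)) for name in PARAM_NAMES}
    hyper_out = {f"{name}_g": np.empty((cfg.chains, cfg.n_keep)) for name in PARAM_NAMES}
    sd_out = {f"sigma_{name}": np.empty((cfg.chains, cfg.n_keep)) for name in PARAM_NAMES}
    accept = np.zeros((cfg.chains, 4))

    for chain in range(cfg.chains):
        rng = _chain_rng(cfg.seed, chain)
        thetas = theta_init.copy()
        mu = thetas.mean(axis=0)
        var0 = np.maximum(thetas.var(axis=0), [0.25, 1e-6, 25.0, 1e-4])
        tau = 1.0 / var0
        tau[1] = min(max(tau[1], priors.tau_s_bounds[0]), priors.tau_s_bounds[1])

        logliks = np.empty(n)
        for i, d in enumerate(datas):
            logliks[i] = _loglik(d, thetas[i], base, c)
            if not np.isfinite(logliks[i]):
                thetas[i] = _default_init(d, base)
                logliks[i] = _loglik(d, thetas[i], base, c)
            if not np.isfinite(logliks[i]):
                raise RuntimeError(f"no valid starting point for subject {datas[i].id}")

        scales = np.tile(np.array(cfg.proposal_scales, dtype=float), (n, 1))
        window = np.zeros((n, 4))
        kept = 0
        for it in range(cfg.iterations):
            sds = 1.0 / np.sqrt(tau)
            # --- individual parameters: Metropolis within Gibbs
            for i, d in enumerate(datas):
                theta = thetas[i]
                for j in range(4):
                    prop = theta.copy()
                    prop[j] += scales[i, j] * rng.standard_normal()
                    if not _in_support(prop, base):
                        continue
                    ll_prop = _loglik(d, prop, base, c)
                    if not np.isfinite(ll_prop):
                        continue
                    dz = ((prop[j] - mu[j]) ** 2 - (theta[j] - mu[j]) ** 2) * tau[j]
                    log_ratio = ll_prop - logliks[i] - 0.5 * dz
                    if log_ratio > math.log(rng.uniform()):
                        theta[j] = prop[j]
                        logliks[i] = ll_prop
                        window[i, j] += 1
                        if it >= cfg.burn_in:
                            accept[chain, j] += 1
            # --- hypermeans
            for j, name in enumerate(PARAM_NAMES):
                mean_j = float(thetas[:, j].mean())
                if name == "S":
                    p0 = 1.0 / base.s_sd**2
                    pn = p0 + n * tau[j]
                    post_mean = (p0 * base.s_mean + tau[j] * thetas[:, j].sum()) / pn
                    mu[j] = rng.normal(post_mean, 1.0 / math.sqrt(pn))
                else:
                    lo, hi = hyper_bounds[name]
                    mu[j] = _trunc_normal(rng, mean_j, 1.0 / math.sqrt(n * tau[j]), lo, hi)
            # --- precisions
            ss = ((thetas - mu) ** 2).sum(axis=0)
            for j, name in enumerate(PARAM_NAMES):
                if name == "S":
                    tau[j] = _trunc_gamma(
                        rng, 0.5 * n + 1.0, 0.5 * ss[j] + 1e-300, *priors.tau_s_bounds
                    )
                else:
                    tau[j] = rng.gamma(
                        priors.tau_shape + 0.5 * n, 1.0 / (priors.tau_rate + 0.5 * ss[j])
                    )
            if it < cfg.burn_in and (it + 1) % cfg.adapt_interval == 0:
                rates = window / cfg.adapt_interval
                scales *= np.exp(rates - cfg.target_accept)
                window[:] = 0.0
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
                for j, name in enumerate(PARAM_NAMES):
                    out[name][chain, kept] = thetas[:, j]
                    hyper_out[f"{name}_g"][chain, kept] = mu[j]
                    sd_out[f"sigma_{name}"][chain, kept] = 1.0 / math.sqrt(tau[j])
                kept += 1

    draws = dict(out)
    draws.update(hyper_out)
    draws.update(sd_out)
    draws["TEE"] = c.weir_factor * draws["rCO2"]
    draws["TEE_g"] = c.weir_factor * draws["rCO2_g"]
    n_post = cfg.iterations - cfg.burn_in
    rates = {
        name: float(accept[:, j].sum()) / (cfg.chains * n_post * n)
        for j, name in enumerate(PARAM_NAMES)
    }
    _check_acceptance(rates, f"hierarchical ({n} subjects)")
    diagnostics = {"acceptance_rates": rates}
    diagnostics.update(convergence_diagnostics({k: draws[k] for k in ("S_g", "rCO2_g")}))
    return PosteriorResult(
        draws=draws, config=cfg, subject_ids=[s.id for s in subjects], diagnostics=diagnostics
    )


def convergence_diagnostics(draws: dict[str, np.ndarray]) -> dict:
    """Split-chain R-hat and bulk effective sample size per parameter."""
    import logging

    import arviz as az

    logging.getLogger("arviz").setLevel(logging.ERROR)

    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, a in draws.items():
            single_chain = a.shape[0] < 2
            if a.ndim == 2:
                rhat[name] = np.nan if single_chain else float(az.rhat(a))
                ess[name] = float(az.ess(a))
            else:
                rhat[name] = np.nan if single_chain else float(np.max(az.rhat(a).x.values))
                ess[name] = float(np.min(az.ess(a).x.values))
    flagged = [k for k, v in rhat.items() if v > 1.05]
    if flagged:
        warnings.warn(f"R-hat above 1.05 for: {', '.join(flagged)}", stacklevel=3)
    return {"rhat": rhat, "ess": ess}


def summarize(result: PosteriorResult, c: ModelConstants = DEFAULT_CONSTANTS):
    """Posterior summary table: mean, sd, median, CV and central 95% interval.

    Per-subject parameters of cohort runs are expanded one row per subject;
    cohort rows additionally report the across-subject min-max of the
    per-subject posterior medians.
    """
    import pandas as pd

    rows = []
    for name, a in result.draws.items():
        if a.size == 0:
            raise ValueError("posterior contains no draws")
        if a.ndim == 2:
            flat = a.reshape(-1)
            rows.append(_summary_row(name, None, flat))
        else:
            for s_idx in range(a.shape[2]):
                sid = result.subject_ids[s_idx] if result.subject_ids else str(s_idx)
                rows.append(_summary_row(name, sid, a[:, :, s_idx].reshape(-1)))
    return pd.DataFrame(rows)


def _summary_row(name: str, subject: str | None, flat: np.ndarray) -> dict:
    mean = float(flat.mean())
    sd = float(flat.std(ddof=1)) if flat.size > 1 else 0.0
    q = np.percentile(flat, [2.5, 50.0, 97.5])
    return {
        "parameter": name,
        "subject": subject,
        "mean": mean,
        "sd": sd,
        "median": float(q[1]),
        "cv": sd / abs(mean) if mean != 0 else np.nan,
        "q2.5": float(q[0]),
        "q97.5": float(q[2]),
    }


def subject_medians(result: PosteriorResult, name: str) -> np.ndarray:
    """Per-subject posterior medians for a cohort parameter."""
    a = result.draws[name]
    if a.ndim != 3:
        raise ValueError(f"{name} is not a per-subject parameter")
    return np.median(a.reshape(-1, a.shape[2]), axis=0)
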