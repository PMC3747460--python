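"""Calibrating the conditional log-hazard ratio to a marginal target.

Hazard ratios are non-collapsible: with covariate effects on the
outcome, the population-average (marginal) hazard ratio induced by a
conditional log-hazard ratio ``beta_treat`` is attenuated toward the
null relative to ``exp(beta_treat)``.  To simulate data with a *known
marginal* hazard ratio, this module estimates the marginal log-HR
induced by a candidate ``beta_treat`` via potential-outcomes
simulation — every subject contributes an event time under treatment
and one under control, and a univariate Cox model is fitted to the
stacked sample — and inverts the (monotone) map by bisection.

Two framings are supported: ATE, where the stacked sample contains the
whole population, and ATT, where it is restricted to subjects whose
realized treatment assignment was active treatment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cox import CoxError, cox_fit
from .datagen import (OutcomeModel, ScenarioConfig, TreatmentModel,
                      assign_treatment, calibrate_treatment_intercept,
                      generate_covariates, generate_event_times)

DEFAULT_TOL = 0.005            # log-HR scale; below the MC noise at default reps
DEFAULT_MC_REPS = 1000
MAX_BRACKET = 5.0              # |beta| beyond this means the model is misconfigured

# parameters the shipped calibration cache was computed with
# (scripts/build_calibration_cache.py)
PACKAGED_MC_REPS = 200
PACKAGED_SEED = 0


@dataclass
class CalibrationResult:
    """Calibrated conditional log-HR and its diagnostics."""

    target_marginal_hr: float
    estimand: str
    beta_treat: float
    achieved_marginal_loghr: float
    mc_se: float
    n_iterations: int
    trace: list = field(default_factory=list)
    n_mc_reps: int = 0
    n_subjects: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("target_marginal_hr", "estimand", "beta_treat",
                 "achieved_marginal_loghr", "mc_se", "n_iterations",
                 "trace", "n_mc_reps", "n_subjects")}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(**d)


def estimate_marginal_loghr(beta_treat: float, scenario: ScenarioConfig,
                            n_mc_reps: int, rng,
                            *, estimand: str | None = None,
                            intercept: float | None = None):
    """Marginal log-HR induced by ``beta_treat`` under a scenario.

    For each replicate a cohort is generated and *both* potential event
    times are drawn per subject (treatment forced off and on, same
    covariates, independent uniforms per arm).  A univariate Cox model
    on the stacked sample of both arms gives the marginal log-HR; the
    ATT framing first restricts the stack to subjects whose realized
    assignment was treatment.  Returns ``(mean, mc_se)`` across
    replicates.
    """
    if n_mc_reps < 1:
        raise ValueError("n_mc_reps must be at least 1")
    estimand = scenario.estimand if estimand is None else estimand
    if intercept is None:
        intercept = calibrate_treatment_intercept(scenario.prop_treated)
    tmodel = TreatmentModel(intercept)
    omodel = OutcomeModel(beta_treat)
    g = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = scenario.n_subjects
    coefs = []
    failures = 0
    for _ in range(n_mc_reps):
        X = generate_covariates(n, g)
        z = assign_treatment(X, tmodel, g)
        t0 = generate_event_times(X, np.zeros(n), omodel, g)
        t1 = generate_event_times(X, np.ones(n), omodel, g)
        if estimand == "ATT":
            keep = z == 1
            t0, t1 = t0[keep], t1[keep]
        times = np.concatenate([t0, t1])
        arm = np.r_[np.zeros(t0.shape[0]), np.ones(t1.shape[0])]
        try:
            fit = cox_fit(times, np.ones(times.shape[0], dtype=int), arm)
        except CoxError:
            fit = None
        if fit is None or not fit.converged:
            failures += 1
            warnings.warn("stacked Cox fit failed in a calibration replicate",
                          RuntimeWarning)
            continue
        coefs.append(fit.coef[0])
    if failures > 0.05 * n_mc_reps:
        raise RuntimeError(f"{failures}/{n_mc_reps} calibration replicates failed")
    coefs = np.asarray(coefs)
    mc_se = float(coefs.std(ddof=1) / np.sqrt(coefs.shape[0])) \
        if coefs.shape[0] > 1 else np.nan
    return float(coefs.mean()), mc_se


def calibrate_conditional_beta(target_marginal_hr: float, estimand: str,
                               scenario: ScenarioConfig,
                               *, tol: float = DEFAULT_TOL,
                               n_mc_reps: int = DEFAULT_MC_REPS,
                               seed=None) -> CalibrationResult:
    """Bisection for the conditional log-HR inducing a marginal target.

    The marginal log-HR is monotone increasing in ``beta_treat``; the
    initial bracket is centered on ``log(target)`` and widened
    adaptively if it does not straddle the root.  Iteration stops once
    the bracket half-width falls below ``tol``.
    """
    if target_marginal_hr <= 0:
        raise ValueError("target_marginal_hr must be positive")
    if tol <= 0:
        raise ValueError("tol must be positive")
    theta = float(np.log(target_marginal_hr))
    intercept = calibrate_treatment_intercept(scenario.prop_treated)
    ss = np.random.SeedSequence(seed if seed is not None else scenario.seed)

    def f(beta: float) -> float:
        g = np.random.default_rng(ss.spawn(1)[0])
        est, _ = estimate_marginal_loghr(beta, scenario, n_mc_reps, g,
                                         estimand=estimand, intercept=intercept)
        return est - theta

    lo = theta - 0.5 * abs(theta) - 0.1
    hi = theta + 0.5 * abs(theta) + 0.1
    trace: list = []
    f_lo, f_hi = f(lo), f(hi)
    trace.append({"lo": lo, "hi": hi, "f_lo": f_lo, "f_hi": f_hi})
    while f_lo > 0:
        lo -= (hi - lo)
        if abs(lo) > MAX_BRACKET:
            raise RuntimeError("bracket expansion exceeded +-5 on the log-HR "
                               "scale; outcome model looks misconfigured")
        f_lo = f(lo)
        trace.append({"lo": lo, "hi": hi, "f_lo": f_lo, "f_hi": f_hi})
    while f_hi < 0:
        hi += (hi - lo)
        if abs(hi) > MAX_BRACKET:
            raise RuntimeError("bracket expansion exceeded +-5 on the log-HR "
                               "scale; outcome model looks misconfigured")
        f_hi = f(hi)
        trace.append({"lo": lo, "hi": hi, "f_lo": f_lo, "f_hi": f_hi})
    n_iter = 0
    while (hi - lo) / 2.0 > tol:
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        n_iter += 1
        if f_mid < 0:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
        trace.append({"lo": lo, "hi": hi, "mid": mid, "f_mid": f_mid})
    beta = 0.5 * (lo + hi)
    g = np.random.default_rng(ss.spawn(1)[0])
    achieved, mc_se = estimate_marginal_loghr(beta, scenario, n_mc_reps, g,
                                              estimand=estimand,
                                              intercept=intercept)
    return CalibrationResult(
        target_marginal_hr=float(target_marginal_hr), estimand=estimand,
        beta_treat=float(beta), achieved_marginal_loghr=float(achieved),
        mc_se=mc_se, n_iterations=n_iter, trace=trace,
        n_mc_reps=n_mc_reps, n_subjects=scenario.n_subjects)


# ---------------------------------------------------------------------------
# JSON cache so each (target HR, estimand, prevalence) is calibrated once


def cache_key(target_hr: float, estimand: str, prop_treated: float,
              n_subjects: int, n_mc_reps: int, seed) -> str:
    return (f"hr={target_hr:g}|estimand={estimand}|prev={prop_treated:g}"
            f"|n={n_subjects}|reps={n_mc_reps}|seed={seed}")


def load_cache(path) -> dict:
    path = Path(path)
    if not path.exists():
        return {}
    with open(path) as fh:
        raw = json.load(fh)
    return {k: CalibrationResult.from_dict(v) for k, v in raw.items()}


def save_cache(cache: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in cache.items()}, fh, indent=1)


def packaged_cache_path() -> Path:
    """Calibrations shipped with the package (precomputed by its own code)."""
    return Path(__file__).parent / "data" / "calibration_cache.json"


def calibrated_beta(target_hr: float, estimand: str, prop_treated: float,
                    *, n_subjects: int = 10_000,
                    n_mc_reps: int = DEFAULT_MC_REPS, seed=0,
                    cache_path=None, compute_if_missing: bool = True,
                    tol: float = DEFAULT_TOL) -> CalibrationResult:
    """Look up (or compute and cache) a calibration."""
    path = packaged_cache_path() if cache_path is None else Path(cache_path)
    cache = load_cache(path)
    key = cache_key(target_hr, estimand, prop_treated, n_subjects,
                    n_mc_reps, seed)
    if key in cache:
        return cache[key]
    if not compute_if_missing:
        raise KeyError(f"no cached calibration for {key}")
    scenario = ScenarioConfig(prop_treated=prop_treated,
                              target_marginal_hr=target_hr,
                              estimand=estimand, n_subjects=n_subjects,
                              seed=seed)
    res = calibrate_conditional_beta(target_hr, estimand, scenario,
                                     tol=tol, n_mc_reps=n_mc_reps, seed=seed)
    cache[key] = res
    try:
        save_cache(cache, path)
    except OSError:  # pragma: no cover - read-only installs
        warnings.warn(f"could not write calibration cache at {path}")
    return res


def packaged_beta(target_hr: float, estimand: str, prop_treated: float,
                  *, n_subjects: int = 10_000,
                  cache_path=None) -> CalibrationResult:
    """Calibration from the shipped cache (raises KeyError if absent)."""
    return calibrated_beta(target_hr, estimand, prop_treated,
                           n_subjects=n_subjects, n_mc_reps=PACKAGED_MC_REPS,
                           seed=PACKAGED_SEED, cache_path=cache_path,
                           compute_if_missing=False)


def grid_beta_lookup(estimand: str, prevalences, marginal_hrs,
                     *, n_subjects: int = 10_000, cache_path=None) -> dict:
    """(prevalence, hr) -> conditional log-HR for a whole factorial grid."""
    return {(p, h): packaged_beta(h, estimand, p, n_subjects=n_subjects,
                                  cache_path=cache_path).beta_treat
            for p in prevalences for h in marginal_hrs}
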