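"""Replication loop, performance metrics, and the scenario grid.

``run_scenario`` simulates many cohorts under one design cell
(treatment prevalence x target marginal hazard ratio x estimand),
applies the requested hazard-ratio estimators to each cohort, and
aggregates the per-replicate estimates into the standard Monte Carlo
performance battery: bias, relative bias, MSE, mean estimated SE,
empirical SD, SE/SD ratio, 95% CI coverage and mean CI length.

``run_grid`` runs the full factorial (three prevalences x seven
marginal hazard ratios in the reference design) and writes tidy CSV
output plus a JSON manifest of seeds and calibrations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import calibration as _cal
from .datagen import (CohortDataset, OutcomeModel, ScenarioConfig,
                      TreatmentModel, calibrate_treatment_intercept,
                      simulate_cohort)
from .estimators import (METHODS, EffectEstimate, estimate_covadj,
                         estimate_iptw, estimate_matched, estimate_stratified)
from .psmethods import (fit_propensity_model, greedy_caliper_match,
                        iptw_weights, quintile_strata)

DEFAULT_PREVALENCES = (0.05, 0.10, 0.25)
DEFAULT_MARGINAL_HRS = (0.8, 1.0, 1.10, 1.25, 1.50, 1.75, 2.0)


@dataclass
class MethodPerformance:
    """Aggregated Monte Carlo performance of one method in one scenario."""

    method: str
    scenario_id: str
    mean_loghr: float
    bias: float
    relative_bias_pct: float | None
    mse: float
    mean_se: float
    empirical_sd: float
    se_sd_ratio: float
    coverage: float
    mean_ci_length_hr: float
    mean_ci_length_log: float
    mc_se_mean: float
    n_reps: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class ScenarioResult:
    scenario: ScenarioConfig
    beta_treat: float
    performances: list = field(default_factory=list)
    avg_matched_pairs: float = np.nan
    matched_fraction: float = np.nan
    estimates: pd.DataFrame | None = None

    def performance(self, method: str) -> MethodPerformance:
        for p in self.performances:
            if p.method == method:
                return p
        raise KeyError(method)

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.to_dict() for p in self.performances])


def scenario_id(scenario: ScenarioConfig) -> str:
    return (f"prev{scenario.prop_treated:g}_hr{scenario.target_marginal_hr:g}"
            f"_{scenario.estimand.lower()}")


def compute_metrics(estimates: list[EffectEstimate], theta: float,
                    scenario_label: str = "") -> MethodPerformance:
    """Aggregate per-replicate estimates against the true log-HR ``theta``.

    Relative bias is reported as ``100 * bias / theta`` and omitted when
    ``theta`` is zero (null hazard ratio).  CI length is averaged on the
    hazard-ratio scale (exponentiated endpoints); the log-scale mean
    length is recorded alongside.
    """
    est = [e for e in estimates if e.converged]
    if len(est) == 0:
        raise ValueError("no converged estimates")
    if len(est) < 2:
        raise ValueError("need at least 2 converged estimates")
    loghr = np.array([e.loghr for e in est])
    se = np.array([e.se for e in est])
    lo = np.array([e.ci_low for e in est])
    hi = np.array([e.ci_high for e in est])
    mean = float(loghr.mean())
    bias = mean - theta
    sd = float(loghr.std(ddof=1))
    mean_se = float(se.mean())
    return MethodPerformance(
        method=est[0].method, scenario_id=scenario_label,
        mean_loghr=mean, bias=float(bias),
        relative_bias_pct=None if theta == 0 else float(100.0 * bias / theta),
        mse=float(np.mean((loghr - theta) ** 2)),
        mean_se=mean_se, empirical_sd=sd,
        se_sd_ratio=float(mean_se / sd) if sd > 0 else np.inf,
        coverage=float(np.mean((lo <= theta) & (theta <= hi))),
        mean_ci_length_hr=float(np.mean(np.exp(hi) - np.exp(lo))),
        mean_ci_length_log=float(np.mean(hi - lo)),
        mc_se_mean=float(sd / np.sqrt(len(est))),
        n_reps=len(est))


def coverage_significance_bounds(n_reps: int, level: float = 0.95):
    """Binomial bounds outside which empirical coverage differs
    significantly from the nominal level (normal approximation)."""
    half = 1.96 * np.sqrt(level * (1 - level) / n_reps)
    return level - half, level + half


def run_replicate(cohort: CohortDataset, methods, rng) -> dict:
    """Apply the requested estimators to one simulated cohort.

    Returns per-method :class:`EffectEstimate` plus matched-sample
    bookkeeping under the ``"_pairs"`` / ``"_n_treated"`` keys.
    """
    out: dict = {}
    ps = fit_propensity_model(cohort.X, cohort.z)
    need_match = any(m.startswith("matched") for m in methods)
    need_strata = any(m.startswith("strat") for m in methods)
    if need_match:
        matched = greedy_caliper_match(ps.logit_ps, cohort.z, 0.2, rng)
        out["_pairs"] = matched.n_pairs
        out["_n_treated"] = cohort.n_treated
        for m in ("matched-naive", "matched-robust", "matched-stratified"):
            if m in methods:
                out[m] = estimate_matched(cohort, matched, m.split("-")[1])
    if need_strata:
        strata = quintile_strata(ps.ps)
        for m in ("strat-adjusted", "strat-pooled", "strat-stratified"):
            if m in methods:
                out[m] = estimate_stratified(cohort, strata, m.split("-")[1])
    if "iptw-ate" in methods:
        out["iptw-ate"] = estimate_iptw(cohort, iptw_weights(ps.ps, cohort.z, "ATE"))
    if "iptw-att" in methods:
        out["iptw-att"] = estimate_iptw(cohort, iptw_weights(ps.ps, cohort.z, "ATT"))
    if "cov-adjust" in methods:
        out["cov-adjust"] = estimate_covadj(cohort, ps)
    return out


def _one_replicate(seed_seq, n_subjects, intercept, beta_treat, methods):
    rng = np.random.default_rng(seed_seq)
    cohort = simulate_cohort(n_subjects, TreatmentModel(intercept),
                             OutcomeModel(beta_treat), rng)
    try:
        return run_replicate(cohort, methods, rng)
    except Exception as exc:   # noqa: BLE001 - logged, counted by caller
        return {"_error": str(exc)}


def run_scenario(scenario: ScenarioConfig, methods=METHODS, *,
                 beta_treat: float | None = None,
                 calibration_cache=None, n_jobs: int = 1,
                 keep_estimates: bool = False) -> ScenarioResult:
    """Simulate ``scenario.n_reps`` cohorts and aggregate all methods.

    ``beta_treat`` (the conditional log-HR of the data-generating
    process) is looked up in the calibration cache when not given.  Each
    replicate draws from its own seed substream spawned from the
    scenario seed, so results are identical for any worker count.
    """
    methods = tuple(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if beta_treat is None:
        res = _cal.packaged_beta(scenario.target_marginal_hr,
                                 scenario.estimand, scenario.prop_treated,
                                 n_subjects=scenario.n_subjects,
                                 cache_path=calibration_cache)
        beta_treat = res.beta_treat
    intercept = calibrate_treatment_intercept(scenario.prop_treated)
    seeds = np.random.SeedSequence(scenario.seed).spawn(scenario.n_reps)
    if n_jobs == 1:
        reps = [_one_replicate(s, scenario.n_subjects, intercept, beta_treat,
                               methods) for s in seeds]
    else:
        reps = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(s, scenario.n_subjects, intercept,
                                    beta_treat, methods) for s in seeds)
    failures = [r for r in reps if "_error" in r]
    if len(failures) > 0.05 * scenario.n_reps:
        raise RuntimeError(f"{len(failures)}/{scenario.n_reps} replicates "
                           f"failed; first error: {failures[0]['_error']}")
    if failures:
        warnings.warn(f"{len(failures)} replicates failed and were dropped")
    good = [r for r in reps if "_error" not in r]
    theta = float(np.log(scenario.target_marginal_hr))
    sid = scenario_id(scenario)
    performances = []
    for m in methods:
        ests = [r[m] for r in good if m in r]
        performances.append(compute_metrics(ests, theta, sid))
    pairs = np.array([r["_pairs"] for r in good if "_pairs" in r], float)
    ntr = np.array([r["_n_treated"] for r in good if "_n_treated" in r], float)
    result = ScenarioResult(
        scenario=scenario, beta_treat=float(beta_treat),
        performances=performances,
        avg_matched_pairs=float(pairs.mean()) if pairs.size else np.nan,
        matched_fraction=float((pairs / ntr).mean()) if pairs.size else np.nan)
    if keep_estimates:
        rows = []
        for i, r in enumerate(good):
            for m in methods:
                if m in r:
                    e = r[m]
                    rows.append({"scenario": sid, "replicate": i, "method": m,
                                 "loghr": e.loghr, "se": e.se,
                                 "ci_low": e.ci_low, "ci_high": e.ci_high,
                                 "converged": e.converged})
        result.estimates = pd.DataFrame(rows)
    return result


def run_grid(prevalences=DEFAULT_PREVALENCES, marginal_hrs=DEFAULT_MARGINAL_HRS,
             estimand: str = "ATT", n_reps: int = 100, seed: int = 0, *,
             n_subjects: int = 10_000, methods=METHODS, output_dir=None,
             calibration_cache=None, n_jobs: int = 1,
             beta_lookup: dict | None = None) -> list[ScenarioResult]:
    """Run the factorial scenario grid and optionally write tidy output.

    ``beta_lookup`` maps ``(prevalence, hr)`` to a pre-calibrated
    conditional log-HR, bypassing the cache.
    """
    prevalences = tuple(prevalences)
    marginal_hrs = tuple(marginal_hrs)
    if not prevalences or not marginal_hrs:
        raise ValueError("prevalence and hazard-ratio lists must be non-empty")
    results = []
    root = np.random.SeedSequence(seed)
    scen_seeds = root.spawn(len(prevalences) * len(marginal_hrs))
    k = 0
    for prev in prevalences:
        for hr in marginal_hrs:
            scen = ScenarioConfig(prop_treated=prev, target_marginal_hr=hr,
                                  estimand=estimand, n_subjects=n_subjects,
                                  n_reps=n_reps,
                                  seed=int(scen_seeds[k].generate_state(1)[0] % (2 ** 31)))
            k += 1
            beta = None if beta_lookup is None else beta_lookup[(prev, hr)]
            results.append(run_scenario(scen, methods, beta_treat=beta,
                                        calibration_cache=calibration_cache,
                                        n_jobs=n_jobs))
    if output_dir is not None:
        write_grid_output(results, output_dir, master_seed=seed)
    return results


def grid_metrics_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """One tidy row per scenario x method."""
    rows = []
    for r in results:
        for p in r.performances:
            d = p.to_dict()
            d.update({"prop_treated": r.scenario.prop_treated,
                      "target_marginal_hr": r.scenario.target_marginal_hr,
                      "estimand": r.scenario.estimand,
                      "beta_treat": r.beta_treat,
                      "avg_matched_pairs": r.avg_matched_pairs,
                      "matched_fraction": r.matched_fraction})
            rows.append(d)
    return pd.DataFrame(rows)


def write_grid_output(results: list[ScenarioResult], output_dir,
                      master_seed=None) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid_metrics_frame(results).to_csv(out / "metrics.csv", index=False)
    manifest = {"master_seed": master_seed, "scenarios": [
        {"id": scenario_id(r.scenario), **r.scenario.to_dict(),
         "beta_treat": r.beta_treat} for r in results]}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    for r in results:
        if r.estimates is not None:
            r.estimates.to_csv(out / f"estimates_{scenario_id(r.scenario)}.csv",
                               index=False)
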