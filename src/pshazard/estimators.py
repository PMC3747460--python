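"""The nine hazard-ratio estimators.

Every estimator is a Cox regression for the treatment indicator on top
of one of the propensity-score conditioning designs:

matched sample      -> ``matched-naive`` (model-based SE),
                       ``matched-robust`` (pair-clustered sandwich SE),
                       ``matched-stratified`` (baseline hazard per pair);
quintile strata     -> ``strat-adjusted`` (stratum dummies as covariates),
                       ``strat-pooled`` (average of stratum-specific fits),
                       ``strat-stratified`` (baseline hazard per stratum);
IPTW                -> ``iptw-ate`` / ``iptw-att`` (weighted fit, robust SE);
covariate adjusted  -> ``cov-adjust`` (treatment + PS as covariates).

Matching, weighting, and the naive/robust matched fits target marginal
(population-average) hazard ratios; the stratified, pair-stratified and
covariate-adjusted fits condition on their design variable and return
conditional-flavored estimates — comparing the two families is the
whole point of the simulation framework.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import CoxError, check_two_arm_events, cox_fit
from .datagen import CohortDataset
from .psmethods import MatchedSample, PropensityScores, StratumAssignment, WeightVector

Z95 = 1.96

METHODS = ("matched-naive", "matched-robust", "matched-stratified",
           "strat-adjusted", "strat-pooled", "strat-stratified",
           "iptw-ate", "iptw-att", "cov-adjust")

#: methods whose target is the marginal (population-average) hazard ratio
MARGINAL_METHODS = ("matched-naive", "matched-robust", "iptw-ate", "iptw-att")


@dataclass
class CoxFitSpec:
    """Declarative description of one Cox fit.

    ``covariates`` are column names in the data frame, treatment first;
    ``variance`` is ``"model"``, ``"robust"`` or ``"cluster"`` (the
    latter requires ``cluster``); ``weights`` names an observation-weight
    column and requires a robust variance.
    """

    covariates: tuple
    strata: str | None = None
    variance: str = "model"
    cluster: str | None = None
    weights: str | None = None

    def __post_init__(self):
        if self.variance not in ("model", "robust", "cluster"):
            raise ValueError("variance must be 'model', 'robust' or 'cluster'")
        if (self.variance == "cluster") != (self.cluster is not None):
            raise ValueError("cluster column required iff variance='cluster'")
        if self.weights is not None and self.variance == "model":
            raise ValueError("weighted fits require a robust variance")


@dataclass
class EffectEstimate:
    """Treatment log-hazard ratio with Wald 95% interval."""

    method: str
    loghr: float
    se: float
    ci_low: float
    ci_high: float
    converged: bool

    @classmethod
    def from_wald(cls, method: str, loghr: float, se: float,
                  converged: bool = True) -> "EffectEstimate":
        return cls(method=method, loghr=float(loghr), se=float(se),
                   ci_low=float(loghr - Z95 * se),
                   ci_high=float(loghr + Z95 * se), converged=bool(converged))

    @property
    def hr(self) -> float:
        return float(np.exp(self.loghr))


def fit_cox(data: pd.DataFrame, spec: CoxFitSpec,
            method: str = "cox") -> EffectEstimate:
    """Common Cox engine behind the nine estimators.

    ``data`` must contain ``time`` and ``event`` columns plus whatever
    ``spec`` references.  The returned estimate is for the first
    covariate in ``spec.covariates`` (the treatment indicator).
    """
    X = data[list(spec.covariates)].to_numpy(float)
    first = data[spec.covariates[0]].to_numpy()
    if np.isin(first, (0, 1)).all():
        check_two_arm_events(data["event"].to_numpy(), first)
    fit = cox_fit(
        data["time"].to_numpy(float), data["event"].to_numpy(int), X,
        weights=None if spec.weights is None else data[spec.weights].to_numpy(float),
        strata=None if spec.strata is None else data[spec.strata].to_numpy(),
        cluster=None if spec.cluster is None else data[spec.cluster].to_numpy(),
        robust=spec.variance == "robust",
    )
    se = fit.se_model[0] if spec.variance == "model" else fit.se_robust[0]
    if not fit.converged:
        warnings.warn(f"Cox fit for '{method}' did not converge", RuntimeWarning)
    return EffectEstimate.from_wald(method, fit.coef[0], se, fit.converged)


def _cohort_frame(cohort: CohortDataset) -> pd.DataFrame:
    return pd.DataFrame({"time": cohort.time, "event": cohort.event,
                         "z": cohort.z})


def estimate_matched(cohort: CohortDataset, matched: MatchedSample,
                     variant: str) -> EffectEstimate:
    """Treatment effect in the 1:1 matched sample.

    ``naive`` and ``robust`` share the same point estimate and differ
    only in the variance (model-based vs pair-clustered sandwich);
    ``stratified`` lets the baseline hazard vary across matched pairs.
    """
    if variant not in ("naive", "robust", "stratified"):
        raise ValueError(f"unknown matched variant {variant!r}")
    if matched.n_pairs == 0:
        raise ValueError("matched sample is empty")
    idx = matched.subject_indices
    df = pd.DataFrame({"time": cohort.time[idx], "event": cohort.event[idx],
                       "z": cohort.z[idx], "pair": matched.pair_ids})
    if variant == "naive":
        spec = CoxFitSpec(covariates=("z",))
    elif variant == "robust":
        spec = CoxFitSpec(covariates=("z",), variance="cluster", cluster="pair")
    else:
        spec = CoxFitSpec(covariates=("z",), strata="pair")
    return fit_cox(df, spec, method=f"matched-{variant}")


def pool_stratum_estimates(loghrs, ses, method: str = "mean"):
    """Combine stratum-specific log-HRs.

    ``mean``: unweighted average with ``SE = sqrt(sum SE_k^2)/K``
    (independent strata); ``ivw``: inverse-variance weighting.
    """
    loghrs = np.asarray(loghrs, float)
    ses = np.asarray(ses, float)
    k = loghrs.shape[0]
    if k == 0:
        raise ValueError("no stratum estimates to pool")
    if method == "mean":
        return float(loghrs.mean()), float(np.sqrt(np.sum(ses ** 2)) / k)
    if method == "ivw":
        w = 1.0 / ses ** 2
        return float(np.sum(w * loghrs) / w.sum()), float(np.sqrt(1.0 / w.sum()))
    raise ValueError(f"unknown pooling method {method!r}")


def estimate_stratified(cohort: CohortDataset, strata: StratumAssignment,
                        variant: str, *, pooling: str = "mean") -> EffectEstimate:
    """Treatment effect under quintile stratification.

    ``adjusted``: one Cox fit with treatment plus four stratum dummies;
    ``pooled``: average of five stratum-specific univariate fits
    (strata without events in both arms are dropped with a warning);
    ``stratified``: univariate fit with stratum-specific baseline hazards.
    """
    if variant not in ("adjusted", "pooled", "stratified"):
        raise ValueError(f"unknown stratification variant {variant!r}")
    df = _cohort_frame(cohort)
    df["stratum"] = strata.labels
    if variant == "adjusted":
        levels = np.unique(strata.labels)
        dummy_cols = []
        for lev in levels[1:]:
            col = f"s{lev}"
            df[col] = (df["stratum"] == lev).astype(float)
            dummy_cols.append(col)
        spec = CoxFitSpec(covariates=("z", *dummy_cols))
        return fit_cox(df, spec, method="strat-adjusted")
    if variant == "stratified":
        spec = CoxFitSpec(covariates=("z",), strata="stratum")
        return fit_cox(df, spec, method="strat-stratified")
    # pooled
    loghrs, ses, ok = [], [], True
    for lev in np.unique(strata.labels):
        sub = df[df["stratum"] == lev]
        ev = sub["event"].to_numpy(bool)
        zz = sub["z"].to_numpy(int)
        if not (ev[zz == 1].any() and ev[zz == 0].any()):
            warnings.warn(f"stratum {lev} has no events in one arm; dropped "
                          "from the pooled estimate")
            continue
        try:
            est = fit_cox(sub, CoxFitSpec(covariates=("z",)), method="stratum")
        except CoxError as exc:
            warnings.warn(f"stratum {lev} fit failed ({exc}); dropped")
            continue
        ok = ok and est.converged
        loghrs.append(est.loghr)
        ses.append(est.se)
    if len(loghrs) < 2:
        raise ValueError("fewer than 2 usable strata for the pooled estimate")
    loghr, se = pool_stratum_estimates(loghrs, ses, method=pooling)
    return EffectEstimate.from_wald("strat-pooled", loghr, se, ok)


def estimate_iptw(cohort: CohortDataset, weights: WeightVector) -> EffectEstimate:
    """Weighted univariate Cox fit with (unclustered) robust sandwich SE."""
    if weights.weights.shape[0] != len(cohort):
        raise ValueError("weight vector does not match cohort size")
    df = _cohort_frame(cohort)
    df["w"] = weights.weights
    spec = CoxFitSpec(covariates=("z",), variance="robust", weights="w")
    return fit_cox(df, spec, method=f"iptw-{weights.estimand.lower()}")


def estimate_covadj(cohort: CohortDataset, ps: PropensityScores) -> EffectEstimate:
    """Cox fit on treatment indicator and the propensity score itself."""
    if ps.ps.shape[0] != len(cohort):
        raise ValueError("propensity scores do not match cohort size")
    df = _cohort_frame(cohort)
    df["ps"] = ps.ps
    if np.ptp(ps.ps) == 0.0:
        # constant PS carries no information; drop it to keep the fit full rank
        spec = CoxFitSpec(covariates=("z",))
    else:
        spec = CoxFitSpec(covariates=("z", "ps"))
    return fit_cox(df, spec, method="cov-adjust")
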