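"""Propensity-score estimation and the three conditioning designs.

Three ways of using an estimated propensity score are constructed here:

* 1:1 greedy nearest-neighbor matching without replacement within a
  caliper on the logit of the propensity score,
* stratification into quintiles of the propensity score,
* inverse-probability-of-treatment weights for the ATE or ATT estimand.

By default the propensity model regresses treatment on the covariates
that affect the outcome (X4..X10), which has been found to give better
treatment-effect estimation than conditioning on the covariates that
drive treatment selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                             PerfectSeparationWarning)

from .datagen import OUTCOME_COLUMNS


@dataclass
class PropensityScores:
    """Fitted treatment-assignment probabilities and their logits."""

    ps: np.ndarray
    logit_ps: np.ndarray
    coef: np.ndarray          # intercept first, then slopes on `columns`
    columns: tuple
    coef_cov: np.ndarray | None = None


@dataclass
class MatchedSample:
    """1:1 matched pairs (indices into the source cohort)."""

    pairs: np.ndarray                 # (k, 2): [treated index, untreated index]
    n_unmatched_treated: int
    caliper: float                    # width actually used, logit-PS units

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])

    @property
    def subject_indices(self) -> np.ndarray:
        """Indices of all retained subjects, treated and untreated interleaved."""
        return self.pairs.reshape(-1)

    @property
    def pair_ids(self) -> np.ndarray:
        """Pair label aligned with :attr:`subject_indices`."""
        return np.repeat(np.arange(self.n_pairs), 2)


@dataclass
class StratumAssignment:
    """Quintile stratum labels 1..5 and the four cut points (PS units)."""

    labels: np.ndarray
    cutpoints: np.ndarray


@dataclass
class WeightVector:
    """Inverse-probability-of-treatment weights for one estimand."""

    weights: np.ndarray
    estimand: str


def fit_propensity_model(X: np.ndarray, z: np.ndarray,
                         columns: tuple | None = None) -> PropensityScores:
    """Maximum-likelihood logistic regression of treatment on covariates.

    ``columns`` are 0-based covariate indices; the default is X4..X10,
    the covariates that affect the outcome.
    """
    X = np.asarray(X, dtype=float)
    z = np.asarray(z, dtype=int)
    if columns is None:
        columns = OUTCOME_COLUMNS
    columns = tuple(columns)
    n1 = int(z.sum())
    if n1 == 0 or n1 == z.shape[0]:
        raise ValueError("need at least one treated and one untreated subject")
    design = sm.add_constant(X[:, columns], has_constant="add")
    model = sm.Logit(z, design)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.simplefilter("error", category=PerfectSeparationWarning)
        try:
            res = model.fit(disp=0, method="newton", tol=1e-10, maxiter=200)
        except (np.linalg.LinAlgError, RuntimeWarning, PerfectSeparationError,
                PerfectSeparationWarning) as exc:
            raise RuntimeError(f"propensity model failed to converge "
                               f"(possible separation): {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("propensity model failed to converge")
    lp = design @ res.params
    ps = 1.0 / (1.0 + np.exp(-lp))
    eps = np.finfo(float).tiny
    ps = np.clip(ps, eps, 1 - 1e-16)
    return PropensityScores(ps=ps, logit_ps=lp, coef=np.asarray(res.params),
                            columns=columns,
                            coef_cov=np.asarray(res.cov_params()))


def _pooled_sd(values: np.ndarray, z: np.ndarray) -> float:
    s1 = np.var(values[z == 1], ddof=1)
    s0 = np.var(values[z == 0], ddof=1)
    return float(np.sqrt((s1 + s0) / 2.0))


def greedy_caliper_match(logit_ps: np.ndarray, z: np.ndarray,
                         caliper_sd_multiple: float = 0.2,
                         rng=None, *, order: str = "random",
                         sd_method: str = "pooled") -> MatchedSample:
    """1:1 greedy nearest-neighbor caliper matching on the logit PS.

    Treated subjects are processed one at a time (random seeded order by
    default) and matched without replacement to the nearest untreated
    subject within the caliper; treated subjects with no available
    neighbor inside the caliper remain unmatched.  The caliper is
    ``caliper_sd_multiple`` times the standard deviation of the logit PS
    (pooled across arms by default, ``sd_method="overall"`` for the
    full-sample SD).  Equidistant candidates are broken toward the lower
    subject index, so results are deterministic given the order.
    """
    logit_ps = np.asarray(logit_ps, dtype=float)
    z = np.asarray(z, dtype=int)
    if caliper_sd_multiple <= 0:
        raise ValueError("caliper_sd_multiple must be positive")
    t_idx = np.flatnonzero(z == 1)
    u_idx = np.flatnonzero(z == 0)
    if u_idx.shape[0] == 0:
        warnings.warn("no untreated subjects; matched sample is empty")
        return MatchedSample(pairs=np.empty((0, 2), dtype=np.intp),
                             n_unmatched_treated=t_idx.shape[0], caliper=np.nan)
    if sd_method not in ("pooled", "overall"):
        raise ValueError(f"unknown sd_method {sd_method!r}")
    if sd_method == "pooled" and t_idx.shape[0] >= 2 and u_idx.shape[0] >= 2:
        sd = _pooled_sd(logit_ps, z)
    else:
        sd = float(np.std(logit_ps, ddof=1))
    caliper = caliper_sd_multiple * sd

    if order == "random":
        g = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        t_order = t_idx[g.permutation(t_idx.shape[0])]
    elif order == "descending":
        t_order = t_idx[np.argsort(-logit_ps[t_idx], kind="stable")]
    elif order == "data":
        t_order = t_idx
    else:
        raise ValueError(f"unknown processing order {order!r}")

    # untreated pool sorted by logit PS; secondary sort on index makes the
    # lower-index tie-break reachable by scanning
    u_sort = u_idx[np.lexsort((u_idx, logit_ps[u_idx]))]
    u_val = logit_ps[u_sort]
    m = u_sort.shape[0]
    # "next available" skip pointers with path compression
    nxt = np.arange(m + 1)          # nxt[i]: smallest available j >= i (self if free)
    prv = np.arange(m)              # prv[i]: largest available j <= i (self if free)

    def find_next(i):
        path = []
        while i <= m - 1 and nxt[i] != i:
            path.append(i)
            i = nxt[i]
        if i > m - 1:
            i = m
        for p_ in path:
            nxt[p_] = i
        return i

    def find_prev(i):
        path = []
        while i >= 0 and prv[i] != i:
            path.append(i)
            i = prv[i]
        if i < 0:
            i = -1
        for p_ in path:
            prv[p_] = i
        return i

    pairs = []
    for ti in t_order:
        v = logit_ps[ti]
        pos = np.searchsorted(u_val, v)
        ri = find_next(pos) if pos <= m - 1 else m
        li = find_prev(min(pos, m) - 1) if pos >= 1 else -1
        d_r = abs(u_val[ri] - v) if ri < m else np.inf
        d_l = abs(v - u_val[li]) if li >= 0 else np.inf
        if d_r < d_l:
            best, dist = ri, d_r
        elif d_l < d_r:
            best, dist = li, d_l
        elif li >= 0 and ri < m:      # exact tie: lower original index
            best = li if u_sort[li] < u_sort[ri] else ri
            dist = d_l
        else:
            best, dist = -1, np.inf
        if best >= 0 and dist <= caliper:
            pairs.append((ti, u_sort[best]))
            nxt[best] = best + 1 if best + 1 <= m else m
            prv[best] = best - 1
            # re-link neighbors lazily via path compression on later queries
        # else: treated subject remains unmatched
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    return MatchedSample(pairs=pairs,
                         n_unmatched_treated=t_idx.shape[0] - pairs.shape[0],
                         caliper=caliper)


def quintile_strata(ps: np.ndarray) -> StratumAssignment:
    """Assign quintile strata 1..5 from the full-sample PS distribution.

    Cut points are the empirical 20/40/60/80th percentiles (linear
    interpolation of order statistics); a value equal to a cut point
    falls in the lower stratum.
    """
    ps = np.asarray(ps, dtype=float)
    if ps.shape[0] < 5:
        raise ValueError("need at least 5 subjects for quintile strata")
    cuts = np.quantile(ps, [0.2, 0.4, 0.6, 0.8], method="linear")
    labels = np.searchsorted(cuts, ps, side="left") + 1
    return StratumAssignment(labels=labels.astype(np.intp), cutpoints=cuts)


def iptw_weights(ps: np.ndarray, z: np.ndarray, estimand: str) -> WeightVector:
    """Inverse-probability-of-treatment weights.

    ATE: ``z/e + (1-z)/(1-e)``; ATT: ``z + e*(1-z)/(1-e)``.  Weights are
    used raw (no truncation or stabilization).
    """
    ps = np.asarray(ps, dtype=float)
    z = np.asarray(z, dtype=int)
    if np.any((ps <= 0) | (ps >= 1)):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    if estimand == "ATE":
        w = z / ps + (1 - z) / (1 - ps)
    elif estimand == "ATT":
        w = z + ps * (1 - z) / (1 - ps)
    else:
        raise ValueError("estimand must be 'ATE' or 'ATT'")
    return WeightVector(weights=w, estimand=estimand)
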