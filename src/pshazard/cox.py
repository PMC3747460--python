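"""Cox proportional-hazards engine.

A small, self-contained fitter for the partial likelihood that supports
exactly the feature union needed by the hazard-ratio estimators in this
package:

* stratified baseline hazards (quintile strata or matched pairs),
* case weights entering the weighted partial likelihood (IPTW fits),
* model-based variance (inverse observed information),
* robust sandwich variance from score residuals, optionally summed
  within clusters (matched pairs).

Estimation is Newton-Raphson with step-halving.  Tied event times are
handled with the Efron correction; for the continuous simulated event
times this package generates, ties are absent almost surely and the
fast vectorized no-tie path is used.  Score residuals (for the sandwich)
use the exact no-tie expressions; with tied events they reduce to the
Breslow-style approximation, which is standard practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class CoxError(ValueError):
    """Raised for structurally unfittable inputs (e.g. no events)."""


@dataclass
class CoxFit:
    """Result of a partial-likelihood fit.

    ``cov_model`` is the inverse observed information; ``cov_robust`` is
    the sandwich estimate (present only when requested).
    """

    coef: np.ndarray
    cov_model: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n: int
    n_events: int
    cov_robust: np.ndarray | None = None
    score_norm: float = field(default=np.nan)

    @property
    def se_model(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_model))

    @property
    def se_robust(self) -> np.ndarray:
        if self.cov_robust is None:
            raise AttributeError("fit was run without robust variance")
        return np.sqrt(np.diag(self.cov_robust))


def _seg_cumsum(v: np.ndarray, starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Cumulative sum along axis 0 restarting at each segment start."""
    cs = np.cumsum(v, axis=0)
    base = np.zeros_like(cs[starts])
    base[1:] = cs[starts[1:] - 1]
    return cs - np.repeat(base, counts, axis=0)


class _CoxData:
    """Pre-sorted design shared across Newton iterations.

    Rows are sorted by (stratum, descending time).  Risk-set sums at a
    subject's event time must include everyone tied at that time, so
    cumulative sums are read at the *last* row of each (stratum, time)
    tie group.
    """

    def __init__(self, time, event, X, weights, strata):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event).astype(int)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = time.shape[0]
        if event.shape[0] != n or X.shape[0] != n:
            raise CoxError("time, event and X must have equal length")
        if n == 0 or event.sum() == 0:
            raise CoxError("no events in the data")
        if np.any(time <= 0):
            raise CoxError("event times must be positive")
        w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        if w.shape[0] != n or np.any(w < 0):
            raise CoxError("weights must be non-negative and match length")
        if strata is None:
            seg = np.zeros(n, dtype=np.intp)
        else:
            _, seg = np.unique(np.asarray(strata), return_inverse=True)
        order = np.lexsort((-time, seg))
        self.order = order
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.X = X[order]
        self.w = w[order]
        self.seg = seg[order]
        self.n, self.p = X.shape
        self.starts = np.flatnonzero(np.r_[True, self.seg[1:] != self.seg[:-1]])
        self.counts = np.diff(np.r_[self.starts, self.n])
        # (stratum, time) tie groups
        change = np.r_[True, (self.seg[1:] != self.seg[:-1])
                       | (self.time[1:] != self.time[:-1])]
        grp = np.cumsum(change) - 1
        gfirst_idx = np.flatnonzero(change)
        glast_idx = np.r_[gfirst_idx[1:] - 1, self.n - 1]
        self.gfirst = gfirst_idx[grp]
        self.glast = glast_idx[grp]
        ev_per_group = np.bincount(grp[self.event], minlength=grp[-1] + 1)
        self.has_ties = bool(np.any(ev_per_group > 1))

    def terms(self, beta: np.ndarray):
        """Log partial likelihood, score vector and observed information."""
        if self.has_ties:
            return self._terms_efron(beta)
        return self._terms_noties(beta)

    def _risk_sums(self, beta):
        eta = self.X @ beta
        eta = eta - eta.max()  # overflow guard; cancels in every ratio and in loglik
        r = self.w * np.exp(eta)
        S0 = _seg_cumsum(r, self.starts, self.counts)[self.glast]
        S1 = _seg_cumsum(r[:, None] * self.X, self.starts, self.counts)[self.glast]
        return eta, r, S0, S1

    def _terms_noties(self, beta):
        eta, r, S0, S1 = self._risk_sums(beta)
        rxx = r[:, None, None] * self.X[:, :, None] * self.X[:, None, :]
        S2 = _seg_cumsum(rxx, self.starts, self.counts)[self.glast]
        ev = self.event
        we = self.w[ev]
        xbar = S1[ev] / S0[ev, None]
        loglik = float(np.sum(we * (eta[ev] - np.log(S0[ev]))))
        grad = (we[:, None] * (self.X[ev] - xbar)).sum(axis=0)
        hmat = S2[ev] / S0[ev, None, None] - xbar[:, :, None] * xbar[:, None, :]
        info = np.einsum("i,ijk->jk", we, hmat)
        return loglik, grad, info

    def _terms_efron(self, beta):
        # slow path, taken only when tied event times exist
        eta = self.X @ beta
        r = self.w * np.exp(eta)
        loglik = 0.0
        grad = np.zeros(self.p)
        info = np.zeros((self.p, self.p))
        for s in range(self.starts.shape[0]):
            lo, hi = self.starts[s], self.starts[s] + self.counts[s]
            t, ev = self.time[lo:hi], self.event[lo:hi]
            Xs, ws, rs = self.X[lo:hi], self.w[lo:hi], r[lo:hi]
            S0, S1 = 0.0, np.zeros(self.p)
            S2 = np.zeros((self.p, self.p))
            i = 0
            while i < t.shape[0]:
                j = i
                while j < t.shape[0] and t[j] == t[i]:
                    j += 1
                idx = slice(i, j)
                S0 += rs[idx].sum()
                S1 += (rs[idx, None] * Xs[idx]).sum(axis=0)
                S2 += np.einsum("i,ij,ik->jk", rs[idx], Xs[idx], Xs[idx])
                d_idx = np.flatnonzero(ev[idx]) + i
                d = d_idx.shape[0]
                if d:
                    T0 = rs[d_idx].sum()
                    T1 = (rs[d_idx, None] * Xs[d_idx]).sum(axis=0)
                    T2 = np.einsum("i,ij,ik->jk", rs[d_idx], Xs[d_idx], Xs[d_idx])
                    wbar = ws[d_idx].mean()
                    loglik += float(np.sum(ws[d_idx] * (Xs[d_idx] @ beta)))
                    grad += (ws[d_idx, None] * Xs[d_idx]).sum(axis=0)
                    for ell in range(d):
                        f = ell / d
                        D0 = S0 - f * T0
                        D1 = S1 - f * T1
                        D2 = S2 - f * T2
                        m = D1 / D0
                        loglik -= wbar * np.log(D0)
                        grad -= wbar * m
                        info += wbar * (D2 / D0 - np.outer(m, m))
                i = j
        return loglik, grad, info

    def score_residuals(self, beta: np.ndarray) -> np.ndarray:
        """Per-subject (unweighted) score residuals in original row order.

        U_i = d_i (x_i - xbar(t_i))
              - exp(eta_i) * sum_{events k: t_k <= t_i} w_k (x_i - xbar(t_k)) / S0(t_k)
        """
        eta, r, S0, S1 = self._risk_sums(beta)
        ev = self.event
        xbar = S1 / S0[:, None]
        a_term = np.where(ev, self.w / S0, 0.0)
        b_term = np.where(ev[:, None], self.w[:, None] * S1 / (S0 ** 2)[:, None], 0.0)
        totA = _seg_cumsum(a_term, self.starts, self.counts)
        totB = _seg_cumsum(b_term, self.starts, self.counts)
        # rows are in descending time, so {t_k <= t_i} spans from the start of
        # i's own tie group through the end of the stratum
        seg_end = self.starts + self.counts - 1
        segtotA = np.repeat(totA[seg_end], self.counts)
        segtotB = np.repeat(totB[seg_end], self.counts, axis=0)
        seg_start_of = np.repeat(self.starts, self.counts)
        at_start = self.gfirst == seg_start_of
        prev = np.maximum(self.gfirst - 1, 0)
        A = segtotA - np.where(at_start, 0.0, totA[prev])
        B = segtotB - np.where(at_start[:, None], 0.0, totB[prev])
        U = (ev[:, None] * (self.X - xbar)
             - np.exp(eta)[:, None] * (self.X * A[:, None] - B))
        out = np.empty_like(U)
        out[self.order] = U
        return out


def cox_fit(time, event, X, *, weights=None, strata=None, cluster=None,
            robust=False, tol=1e-8, max_iter=100) -> CoxFit:
    """Fit a Cox model by maximum partial likelihood.

    Parameters
    ----------
    time, event, X
        Survival time, event indicator (1 = event), covariate matrix
        ``(n, p)`` or a single covariate vector.
    weights
        Optional case weights (weighted partial likelihood).
    strata
        Optional stratum labels: separate baseline hazard per stratum.
    cluster
        Optional cluster labels for the sandwich variance; implies
        ``robust=True``.
    robust
        Compute the score-residual sandwich variance (Lin-Wei / Binder).

    Convergence is declared when the score vector's max-norm falls
    below ``tol``.
    """
    data = _CoxData(time, event, X, weights, strata)
    if cluster is not None:
        robust = True
    beta = np.zeros(data.p)
    loglik, grad, info = data.terms(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        # accept any step that does not decrease the log-likelihood beyond
        # float roundoff at its magnitude
        accept_slack = 1e-9 * max(1.0, abs(loglik))
        for _ in range(40):
            cand = beta + step * delta
            ll_new, g_new, i_new = data.terms(cand)
            if np.isfinite(ll_new) and ll_new - loglik >= -accept_slack:
                beta, loglik, grad, info = cand, ll_new, g_new, i_new
                break
            step *= 0.5
        else:
            break
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True
    if np.any(np.abs(beta) > 15):
        # the likelihood is numerically flat out here: separation / monotone
        # likelihood, e.g. one arm's events all precede the other's
        raise CoxError("monotone partial likelihood; coefficient diverged "
                       "(check that both arms contain events)")
    try:
        cov_model = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_model = np.full((data.p, data.p), np.nan)
        converged = False
    fit = CoxFit(coef=beta, cov_model=cov_model, loglik=loglik, n_iter=it,
                 converged=converged, n=data.n, n_events=int(data.event.sum()),
                 score_norm=float(np.max(np.abs(grad))))
    if robust:
        U = data.score_residuals(beta)           # original order
        worig = np.empty(data.n)
        worig[data.order] = data.w
        G = worig[:, None] * U
        if cluster is not None:
            _, inv = np.unique(np.asarray(cluster), return_inverse=True)
            Gc = np.zeros((inv.max() + 1, data.p))
            np.add.at(Gc, inv, G)
        else:
            Gc = G
        fit.cov_robust = cov_model @ (Gc.T @ Gc) @ cov_model
    return fit


def check_two_arm_events(event, z) -> None:
    """Raise unless both treatment arms contain at least one event."""
    event = np.asarray(event).astype(bool)
    z = np.asarray(z).astype(int)
    if not (event[z == 1].any() and event[z == 0].any()):
        raise CoxError("need at least one event in each treatment arm")


def warn_nonconvergence(fit: CoxFit, label: str) -> None:
    if not fit.converged:
        warnings.warn(f"Cox fit '{label}' did not converge "
                      f"(score norm {fit.score_norm:.2e})", RuntimeWarning)
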