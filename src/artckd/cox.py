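"""Weighted Cox partial likelihood on person-month counting-process data.

The analysis datasets here are person-month tables: every row covers the unit
interval ``(t-1, t]`` on a common monthly grid, so the risk set at event time
``t`` is exactly the set of rows whose ``stop`` equals ``t``.  This engine
exploits that structure to fit weighted proportional-hazards models (Efron tie
handling, Newton-Raphson with step halving) and to return both model-based and
patient-clustered sandwich (robust) covariance matrices fast enough for
Monte-Carlo replicate studies.

Weighted Efron convention: at an event month with ``d`` tied events the
``l``-th sub-denominator removes the fraction ``l/d`` of the event rows'
weighted risk, and each log-denominator term carries the mean event weight,
matching the convention used by standard survival software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .results import FitResult


def _segments(stop_sorted):
    """Contiguous [lo, hi) row segments per unique stop month (sorted input)."""
    uniq, idx = np.unique(stop_sorted, return_index=True)
    bounds = np.append(idx, len(stop_sorted))
    return uniq, bounds


def _efron_terms(Xs, ws, es, eta, bounds, want_resid=False):
    """One pass over all event months.

    Returns (loglik, gradient, hessian) and, when ``want_resid``, per-row
    score residuals in the sorted order.
    """
    n, p = Xs.shape
    r = ws * np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    resid = np.zeros((n, p)) if want_resid else None

    for lo, hi in zip(bounds[:-1], bounds[1:]):
        ev = es[lo:hi]
        d = int(ev.sum())
        if d == 0:
            continue
        Xseg = Xs[lo:hi]
        rseg = r[lo:hi]
        wseg = ws[lo:hi]
        S0 = rseg.sum()
        S1 = rseg @ Xseg
        S2 = (rseg[:, None] * Xseg).T @ Xseg
        Xev = Xseg[ev]
        rev = rseg[ev]
        wev = wseg[ev]
        s0d = rev.sum()
        s1d = rev @ Xev
        s2d = (rev[:, None] * Xev).T @ Xev
        wbar = wev.sum() / d

        ll += float(np.dot(wev, eta[lo:hi][ev]))

        ls = np.arange(d) / d
        Q0 = S0 - ls * s0d                      # (d,)
        Q1 = S1[None, :] - ls[:, None] * s1d    # (d, p)
        mu = Q1 / Q0[:, None]                   # (d, p)
        ll -= wbar * float(np.log(Q0).sum())
        grad += wev @ Xev - wbar * mu.sum(axis=0)
        # Hessian: -wbar * sum_l [ (S2 - (l/d) s2d)/Q0_l - mu_l mu_l' ]
        invQ0 = 1.0 / Q0
        hess -= wbar * (S2 * invQ0.sum() - s2d * float((ls * invQ0).sum()))
        hess += wbar * np.einsum("lp,lq->pq", mu, mu)

        if want_resid:
            xbar = mu.mean(axis=0)
            # non-event rows: c_{il} = 1
            A_ne = invQ0.sum()
            B_ne = invQ0 @ mu
            # event rows: c_{il} = 1 - l/d
            c_ev = 1.0 - ls
            A_ev = float(c_ev @ invQ0)
            B_ev = (c_ev * invQ0) @ mu
            seg_res = -wbar * rseg[:, None] * (A_ne * Xseg - B_ne[None, :])
            if d:
                seg_res[ev] = (
                    wev[:, None] * (Xev - xbar[None, :])
                    - wbar * rev[:, None] * (A_ev * Xev - B_ev[None, :])
                )
            resid[lo:hi] = seg_res

    return ll, grad, hess, resid


def _loglik_pass(Xs, ws, es, beta, bounds, want_resid=False):
    eta = Xs @ beta
    return _efron_terms(Xs, ws, es, eta, bounds, want_resid=want_resid)


def cox_partial_loglik(X, stop, event, weights=None, beta=None):
    """Weighted Efron partial log-likelihood at ``beta`` (oracle-friendly)."""
    X = np.asarray(X, dtype=float)
    stop = np.asarray(stop)
    event = np.asarray(event, dtype=bool)
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    beta = np.zeros(X.shape[1]) if beta is None else np.asarray(beta, dtype=float)
    order = np.argsort(stop, kind="stable")
    _, bounds = _segments(stop[order])
    ll, _, _, _ = _loglik_pass(X[order], w[order], event[order], beta, bounds)
    return ll


@dataclass
class CoxFit:
    """Raw output of the person-month Cox engine."""

    names: list
    beta: np.ndarray
    cov: np.ndarray
    robust_cov: np.ndarray | None
    loglik: float
    loglik_null: float
    n_obs: int
    n_events: int
    iterations: int
    converged: bool
    flags: dict = field(default_factory=dict)

    @property
    def se(self):
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    @property
    def robust_se(self):
        if self.robust_cov is None:
            return None
        return np.sqrt(np.clip(np.diag(self.robust_cov), 0, None))

    def to_result(self, model="", suppressed=(), **diag) -> FitResult:
        res = FitResult.from_estimates(
            self.names, self.beta, self.se, robust_se=self.robust_se,
            suppressed=suppressed, n_obs=self.n_obs, n_events=self.n_events,
            loglik=self.loglik, converged=self.converged, model=model,
        )
        res.diagnostics.update(self.flags)
        res.diagnostics.update(diag)
        return res


def fit_cox_person_months(
    X,
    stop,
    event,
    weights=None,
    cluster=None,
    names=None,
    max_iter=60,
    tol=1e-9,
) -> CoxFit:
    """Fit a weighted Cox model on unit-interval person-month rows.

    Parameters
    ----------
    X : (n, p) array of covariates.
    stop : (n,) integer month index of each row (interval ``(stop-1, stop]``).
    event : (n,) event indicator.
    weights : optional positive per-row weights.
    cluster : optional cluster labels (patient ids) for the sandwich variance;
        when omitted the robust covariance is not computed.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    stop = np.asarray(stop)
    event = np.asarray(event, dtype=bool)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]

    order = np.argsort(stop, kind="stable")
    Xs, ws, es = X[order], w[order], event[order]
    _, bounds = _segments(stop[order])

    # columns with no variation cannot be identified; pin them at zero
    const_cols = np.ptp(Xs, axis=0) == 0
    flags = {}
    if const_cols.any():
        flags["infinite_se_terms"] = [names[j] for j in np.where(const_cols)[0]]
    free = ~const_cols

    beta = np.zeros(p)
    ll, grad, hess, _ = _loglik_pass(Xs, ws, es, beta, bounds)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A = -hess[np.ix_(free, free)]
        g = grad[free]
        try:
            step = np.linalg.solve(A, g)
        except np.linalg.LinAlgError:
            A = A + 1e-8 * np.eye(A.shape[0])
            step = np.linalg.solve(A, g)
            flags["ridge_applied"] = True
        # step halving keeps the partial likelihood monotone
        scale = 1.0
        for _ in range(30):
            cand = beta.copy()
            cand[free] = beta[free] + scale * step
            ll_new, grad_new, hess_new, _ = _loglik_pass(Xs, ws, es, cand, bounds)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, delta = cand, ll_new - ll
        ll, grad, hess = ll_new, grad_new, hess_new
        if abs(delta) < tol and np.linalg.norm(grad[free]) < 1e-6 * max(1, es.sum()):
            converged = True
            break
    if not converged and np.linalg.norm(grad[free]) < 1e-4:
        converged = True  # flat likelihood (e.g. near-separation handled below)
    if np.any(np.abs(beta) > 15):
        drift = [names[j] for j in np.where(np.abs(beta) > 15)[0]]
        flags.setdefault("infinite_se_terms", [])
        flags["infinite_se_terms"] = sorted(set(flags["infinite_se_terms"]) | set(drift))
    if not converged:
        flags["gradient_norm"] = float(np.linalg.norm(grad[free]))

    cov = np.full((p, p), np.nan)
    A = -hess[np.ix_(free, free)]
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        Ainv = np.linalg.pinv(A)
        flags["singular_information"] = True
    cov[np.ix_(free, free)] = Ainv
    cov[~free, ~free] = np.inf

    robust_cov = None
    if cluster is not None:
        _, _, _, resid = _loglik_pass(Xs, ws, es, beta, bounds, want_resid=True)
        cl = np.asarray(cluster)[order]
        codes, inv = np.unique(cl, return_inverse=True)
        U = np.zeros((len(codes), p))
        np.add.at(U, inv, resid)
        meat = U[:, free].T @ U[:, free]
        robust_cov = np.full((p, p), np.nan)
        robust_cov[np.ix_(free, free)] = Ainv @ meat @ Ainv
        robust_cov[~free, ~free] = np.inf

    return CoxFit(
        names=names, beta=beta, cov=cov, robust_cov=robust_cov, loglik=ll,
        loglik_null=ll_null, n_obs=n, n_events=int(es.sum()), iterations=it,
        converged=converged, flags=flags,
    )
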