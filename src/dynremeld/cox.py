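"""Weighted stratified Cox partial-likelihood engine on counting-process data.

The fits this package needs combine features rarely available together in
one routine: interval (start, stop] records with time-varying covariates or
time-varying IPCW weights, stratification by (country x cross-section), a
fixed offset term on the log-hazard scale, case weights, and Efron handling
of the heavy day-granularity ties.  This module implements that directly:
Newton–Raphson on the weighted Efron partial likelihood, with the analytic
gradient and Hessian, and a Breslow-type baseline cumulative hazard per
stratum.

All event times are whole days; risk sets are accumulated with
difference-array prefix sums over a (stratum x day) grid, so one
likelihood/gradient/Hessian evaluation is O(rows + strata x days).

The weighted Efron contribution of stratum ``g`` and event day ``t`` with
death set ``D`` (size ``m``, total weight ``W``) and risk set ``R`` is::

    sum_{i in D} w_i eta_i
      - (W/m) sum_{l=0}^{m-1} log( S0(R) - (l/m) S0(D) )

with ``S0(A) = sum_{j in A} w_j exp(eta_j)`` and ``eta = offset + x'beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CoxFitResult", "fit_cox"]


@dataclass
class CoxFitResult:
    """Maximum partial-likelihood estimates and attached inference.

    ``lr_statistic`` tests the fitted covariates against the all-zero null
    (the offset, when present, is part of both models).
    """

    params: pd.Series
    standard_errors: pd.Series
    covariance: pd.DataFrame
    log_likelihood: float
    null_log_likelihood: float
    n_rows: int
    n_events: int
    n_iter: int
    converged: bool
    baseline_cumhaz: dict = field(default_factory=dict, repr=False)
    strata_labels: list = field(default_factory=list, repr=False)
    naive_covariance: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def df(self) -> int:
        return len(self.params)

    @property
    def lr_statistic(self) -> float:
        return 2.0 * (self.log_likelihood - self.null_log_likelihood)

    @property
    def lr_pvalue(self) -> float:
        return float(stats.chi2.sf(self.lr_statistic, self.df))

    def summary(self) -> pd.DataFrame:
        """Coefficient table: log-HR, SE, z, p, and the hazard ratio."""
        z = self.params / self.standard_errors
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "se(coef)": self.standard_errors,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
                "exp(coef)": np.exp(self.params),
            }
        )
        tab.attrs["log_likelihood"] = self.log_likelihood
        tab.attrs["lr_statistic"] = self.lr_statistic
        tab.attrs["lr_df"] = self.df
        return tab

    def cumhaz_at(self, stratum, times):
        """Baseline cumulative hazard of ``stratum`` evaluated at ``times`` (days)."""
        H = self.baseline_cumhaz[stratum]
        t = np.clip(np.asarray(times, dtype=int), 0, len(H) - 1)
        return H[t]


def _prepare(df, covariates, start_col, stop_col, event_col, weight_col, offset_col, strata_col):
    X = df[list(covariates)].to_numpy(dtype=float)
    stop = np.rint(df[stop_col].to_numpy(dtype=float)).astype(np.int64)
    if start_col is None:
        start = np.zeros(len(df), dtype=np.int64)
    else:
        start = np.rint(df[start_col].to_numpy(dtype=float)).astype(np.int64)
    if np.any(stop <= start):
        raise ValueError("rows must have stop > start")
    d = df[event_col].to_numpy(dtype=bool)
    w = df[weight_col].to_numpy(dtype=float) if weight_col else np.ones(len(df))
    if np.any(w < 0):
        raise ValueError("negative weights")
    o = df[offset_col].to_numpy(dtype=float) if offset_col else np.zeros(len(df))
    if strata_col is None:
        g = np.zeros(len(df), dtype=np.int64)
        labels = ["__all__"]
    else:
        codes, uniques = pd.factorize(df[strata_col], sort=True)
        g, labels = codes.astype(np.int64), list(uniques)
    return X, start, stop, d, w, o, g, labels


class _EfronEngine:
    def __init__(self, X, start, stop, d, w, o, g, n_strata):
        self.X, self.start, self.stop, self.d, self.w, self.o, self.g = X, start, stop, d, w, o, g
        self.n, self.p = X.shape
        self.G = n_strata
        self.T = int(stop.max())
        # event cells: unique (stratum, day) pairs with >= 1 death
        key = g * (self.T + 2) + stop
        ev_keys = np.unique(key[d])
        self.cell_of_key = {k: i for i, k in enumerate(ev_keys)}
        self.cells = ev_keys
        self.ncells = len(ev_keys)
        self.cell_g = ev_keys // (self.T + 2)
        self.cell_t = ev_keys % (self.T + 2)
        # per-cell death counts and weights (beta-independent)
        self.m = np.zeros(self.ncells)
        self.WD = np.zeros(self.ncells)
        didx = np.nonzero(d)[0]
        self.death_cell = np.array([self.cell_of_key[key[i]] for i in didx], dtype=np.int64)
        self.death_rows = didx
        np.add.at(self.m, self.death_cell, 1.0)
        np.add.at(self.WD, self.death_cell, w[didx])
        self.maxm = int(self.m.max()) if self.ncells else 0
        iu = np.triu_indices(self.p)
        self.iu = iu
        self.nq = len(iu[0])

    def _risk_sums(self, vals):
        """Prefix-sum risk-set totals of ``vals`` (n,) at every event cell."""
        grid = np.zeros((self.G, self.T + 2))
        np.add.at(grid, (self.g, self.start + 1), vals)
        np.add.at(grid, (self.g, self.stop + 1), -vals)
        np.cumsum(grid, axis=1, out=grid)
        return grid[self.cell_g, self.cell_t]

    def loglik_grad_hess(self, beta):
        X, w, o, d = self.X, self.w, self.o, self.d
        eta = o + X @ beta
        r = w * np.exp(eta)
        rX = r[:, None] * X
        rXX = rX[:, self.iu[0]] * X[:, self.iu[1]]

        S0R = self._risk_sums(r)
        S1R = np.column_stack([self._risk_sums(rX[:, j]) for j in range(self.p)])
        S2R = np.column_stack([self._risk_sums(rXX[:, q]) for q in range(self.nq)])

        dr = self.death_rows
        S0D = np.zeros(self.ncells)
        np.add.at(S0D, self.death_cell, r[dr])
        S1D = np.zeros((self.ncells, self.p))
        S2D = np.zeros((self.ncells, self.nq))
        for j in range(self.p):
            np.add.at(S1D[:, j], self.death_cell, rX[dr, j])
        for q in range(self.nq):
            np.add.at(S2D[:, q], self.death_cell, rXX[dr, q])

        ll = float(np.sum(w[dr] * eta[dr]))
        grad = (w[dr, None] * X[dr]).sum(axis=0)
        hess = np.zeros((self.p, self.p))
        Wm = self.WD / self.m
        for l in range(self.maxm):
            mask = self.m > l
            phi = (l / self.m[mask])[:, None]
            s0 = S0R[mask] - phi[:, 0] * S0D[mask]
            s1 = S1R[mask] - phi * S1D[mask]
            s2 = S2R[mask] - phi * S2D[mask]
            wml = Wm[mask]
            ll -= float(np.sum(wml * np.log(s0)))
            u = s1 / s0[:, None]
            grad -= (wml[:, None] * u).sum(axis=0)
            # assemble symmetric second-moment term from upper triangle
            v = s2 / s0[:, None] - u[:, self.iu[0]] * u[:, self.iu[1]]
            hq = (wml[:, None] * v).sum(axis=0)
            H = np.zeros((self.p, self.p))
            H[self.iu] = hq
            H = H + H.T - np.diag(np.diag(H))
            hess -= H
        return ll, grad, hess

    def score_residuals(self, beta):
        """Per-row martingale score residuals at ``beta`` (Breslow form).

        ``U_i = w_i d_i (x_i - xbar(t_i)) - r_i * sum_{s_i < t <= t_i} dH(t) (x_i - xbar(t))``
        with ``dH(t) = WD(t)/S0(t)`` and ``xbar = S1/S0``; used for the
        cluster-robust sandwich covariance.
        """
        eta = self.o + self.X @ beta
        r = self.w * np.exp(eta)
        rX = r[:, None] * self.X
        S0R = np.zeros((self.G, self.T + 2))
        np.add.at(S0R, (self.g, self.start + 1), r)
        np.add.at(S0R, (self.g, self.stop + 1), -r)
        np.cumsum(S0R, axis=1, out=S0R)
        S1R = np.zeros((self.G, self.T + 2, self.p))
        for j in range(self.p):
            np.add.at(S1R[:, :, j], (self.g, self.start + 1), rX[:, j])
            np.add.at(S1R[:, :, j], (self.g, self.stop + 1), -rX[:, j])
        np.cumsum(S1R, axis=1, out=S1R)

        dH = np.zeros((self.G, self.T + 1))
        xbar = np.zeros((self.G, self.T + 1, self.p))
        s0c = S0R[self.cell_g, self.cell_t]
        ok = s0c > 0
        dH[self.cell_g[ok], self.cell_t[ok]] = self.WD[ok] / s0c[ok]
        xb = np.zeros((self.ncells, self.p))
        xb[ok] = S1R[self.cell_g[ok], self.cell_t[ok]] / s0c[ok, None]
        xbar[self.cell_g, self.cell_t] = xb
        cumA0 = np.cumsum(dH, axis=1)
        cumA1 = np.cumsum(dH[:, :, None] * xbar, axis=1)

        U = np.zeros((self.n, self.p))
        dr = self.death_rows
        U[dr] = self.w[dr, None] * (self.X[dr] - xb[self.death_cell])
        a0 = cumA0[self.g, self.stop] - cumA0[self.g, self.start]
        a1 = cumA1[self.g, self.stop] - cumA1[self.g, self.start]
        U -= r[:, None] * (self.X * a0[:, None] - a1)
        return U

    def breslow_baseline(self, beta):
        """Per-stratum Breslow cumulative hazard H0[g, 0..T] at ``beta``."""
        eta = self.o + self.X @ beta
        r = self.w * np.exp(eta)
        S0R = self._risk_sums(r)
        inc = np.zeros((self.G, self.T + 1))
        ok = S0R > 0
        inc[self.cell_g[ok], self.cell_t[ok]] = self.WD[ok] / S0R[ok]
        return np.cumsum(inc, axis=1)


def fit_cox(
    df: pd.DataFrame,
    covariates,
    stop_col: str = "time_days",
    event_col: str = "event",
    start_col: str | None = None,
    weight_col: str | None = None,
    offset_col: str | None = None,
    strata_col: str | None = None,
    cluster_col: str | None = None,
    tol: float = 1e-9,
    max_iter: int = 60,
    compute_baseline: bool = True,
) -> CoxFitResult:
    """Fit the weighted stratified Cox model by Newton–Raphson (Efron ties).

    Rows are risk intervals ``(start, stop]`` in whole days with the event
    indicator attached to the interval end.  Strata with no events drop out
    of the partial likelihood automatically.  With ``cluster_col`` the
    reported covariance and standard errors are the cluster-robust sandwich
    (rows of one cluster — typically one patient across cross-sections — are
    correlated); the model-based covariance stays available as
    ``naive_covariance``.
    """
    covariates = list(covariates)
    X, start, stop, d, w, o, g, labels = _prepare(
        df, covariates, start_col, stop_col, event_col, weight_col, offset_col, strata_col
    )
    if not d.any():
        raise ValueError("no events; cannot fit")
    eng = _EfronEngine(X, start, stop, d, w, o, g, len(labels))

    beta = np.zeros(len(covariates))
    ll, grad, hess = eng.loglik_grad_hess(beta)
    ll0 = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design in Cox fit") from exc
        # step-halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, hess_new = eng.loglik_grad_hess(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta, ll_prev = cand, ll
        ll, grad, hess = ll_new, grad_new, hess_new
        if np.max(np.abs(factor * step)) < tol and abs(ll - ll_prev) < 1e-10:
            converged = True
            break

    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular information matrix") from exc
    naive_cov = cov
    if cluster_col is not None:
        U = eng.score_residuals(beta)
        codes, _ = pd.factorize(df[cluster_col], sort=False)
        Ug = np.zeros((codes.max() + 1, U.shape[1]))
        np.add.at(Ug, codes, U)
        cov = naive_cov @ (Ug.T @ Ug) @ naive_cov
    se = np.sqrt(np.clip(np.diag(cov), 0, None))

    baseline = {}
    if compute_baseline:
        H = eng.breslow_baseline(beta)
        baseline = {labels[gi]: H[gi] for gi in range(len(labels))}

    return CoxFitResult(
        params=pd.Series(beta, index=covariates),
        standard_errors=pd.Series(se, index=covariates),
        covariance=pd.DataFrame(cov, index=covariates, columns=covariates),
        log_likelihood=ll,
        null_log_likelihood=ll0,
        n_rows=len(df),
        n_events=int(d.sum()),
        n_iter=it,
        converged=converged,
        baseline_cumhaz=baseline,
        strata_labels=labels,
        naive_covariance=pd.DataFrame(naive_cov, index=covariates, columns=covariates),
    )
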