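"""Inverse-probability-of-censoring weights for transplantation and delisting.

Censoring of waitlist follow-up by transplantation (IPCW-T) and by delisting
(IPCW-D) is informative: both depend on the evolving reported MELD
biomarkers.  Each cause gets a cause-specific proportional-hazards model on
counting-process data — covariates updated at every biomarker report after
the cross-section — treating the other cause and death as plain censoring.
Under conditional independence of the two causes given the covariate
history, the joint weight for a patient at follow-up time ``t`` is::

    w(t) = 1 / ( S_T(t | history) * S_D(t | history) )

optionally *stabilized* by the marginal (covariate-free, stratum-specific)
survival product ``S̄_T(t) * S̄_D(t)`` and truncated at an upper quantile of
the weight distribution.

The default covariates are the UNOS-capped log biomarkers (with the
dialysis creatinine substitution) plus the dialysis indicator, so a
censoring hazard that is log-linear in the reported UNOS-MELD score is
exactly representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cox import CoxFitResult, fit_cox
from .scores import UNOS_MELD, apply_caps

__all__ = [
    "CensoringModel",
    "build_censoring_process",
    "fit_censoring_model",
    "compute_weights",
    "censoring_covariate_columns",
    "CENSORING_COVARIATES",
]

CENSORING_COVARIATES = ["cz_log_crea", "cz_log_bili", "cz_log_inr", "cz_dialysis"]


def censoring_covariate_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Attach the default censoring-model covariates (UNOS-capped logs)."""
    df = df.copy()
    crea = np.where(
        df["dialysis"].astype(bool), UNOS_MELD.dialysis_creatinine, df["creatinine"].astype(float)
    )
    df["cz_log_crea"] = np.log(apply_caps(crea, UNOS_MELD.bounds["creatinine"]))
    df["cz_log_bili"] = np.log(apply_caps(df["bilirubin"].astype(float), UNOS_MELD.bounds["bilirubin"]))
    df["cz_log_inr"] = np.log(apply_caps(df["inr"].astype(float), UNOS_MELD.bounds["inr"]))
    df["cz_dialysis"] = df["dialysis"].astype(float)
    # the implied UNOS-MELD score (capped logs + dialysis substitution) as a
    # single summary covariate, for censoring models driven by the score
    df["cz_score"] = (
        UNOS_MELD.intercept
        + UNOS_MELD.coef_crea * df["cz_log_crea"]
        + UNOS_MELD.coef_bili * df["cz_log_bili"]
        + UNOS_MELD.coef_inr * df["cz_log_inr"]
    )
    return df


@dataclass
class CensoringModel:
    """A fitted cause-specific censoring model with its baseline hazard."""

    cause: str  # "transplant" or "delisting"
    covariates: list
    strata_col: str
    result: CoxFitResult | None  # None for the covariate-free (null) model
    marginal_cumhaz: dict = field(default_factory=dict, repr=False)

    def cumhaz_increment(self, cp: pd.DataFrame) -> np.ndarray:
        """Model-based cumulative-hazard increment over each (t_start, t_stop]."""
        strata = cp[self.strata_col].to_numpy()
        t0 = cp["t_start"].to_numpy(dtype=int)
        t1 = cp["t_stop"].to_numpy(dtype=int)
        if self.result is None:
            eta = np.zeros(len(cp))
            H = self.marginal_cumhaz
            base = {k: v for k, v in H.items()}
        else:
            X = cp[self.covariates].to_numpy(dtype=float)
            eta = X @ self.result.params.to_numpy()
            base = self.result.baseline_cumhaz
        inc = np.zeros(len(cp))
        for s in np.unique(strata):
            m = strata == s
            Hs = base[s]
            hi = np.clip(t1[m], 0, len(Hs) - 1)
            lo = np.clip(t0[m], 0, len(Hs) - 1)
            inc[m] = Hs[hi] - Hs[lo]
        return inc * np.exp(eta)

    def marginal_increment(self, cp: pd.DataFrame) -> np.ndarray:
        strata = cp[self.strata_col].to_numpy()
        t0 = cp["t_start"].to_numpy(dtype=int)
        t1 = cp["t_stop"].to_numpy(dtype=int)
        inc = np.zeros(len(cp))
        for s in np.unique(strata):
            m = strata == s
            Hs = self.marginal_cumhaz[s]
            inc[m] = Hs[np.clip(t1[m], 0, len(Hs) - 1)] - Hs[np.clip(t0[m], 0, len(Hs) - 1)]
        return inc


def build_censoring_process(
    cs_rows: pd.DataFrame,
    reports: pd.DataFrame,
    split_days: int | None = 7,
    frozen_covariates: bool = False,
) -> pd.DataFrame:
    """Counting-process expansion of cross-section rows.

    One interval per covariate-constancy period: breakpoints at every report
    dated strictly after the cross-section (unless ``frozen_covariates``),
    plus an optional regular ``split_days`` grid that bounds how stale an
    evaluated weight can be.  Columns: ``row_id, t_start, t_stop``, the raw
    biomarkers in force, event indicators ``event`` (death),
    ``cens_transplant``, ``cens_delisting`` attached to the final interval.
    """
    rows = cs_rows.reset_index(drop=True).copy()
    rows["row_id"] = np.arange(len(rows))
    keep = ["row_id", "patient_id", "cs_date", "country", "stratum", "time_days",
            "event", "censor_cause", "creatinine", "bilirubin", "inr", "dialysis"]
    base = rows[keep].copy()
    base["offset"] = 0.0

    pieces = [base]
    if not frozen_covariates:
        rep = reports[["patient_id", "report_date", "creatinine", "bilirubin", "inr", "dialysis"]]
        m = rows[["row_id", "patient_id", "cs_date", "country", "stratum", "time_days",
                  "event", "censor_cause"]].merge(rep, on="patient_id", how="inner")
        m["offset"] = (m["report_date"] - m["cs_date"]).dt.days.astype(float)
        m = m[(m["offset"] > 0) & (m["offset"] < m["time_days"])]
        m = m.drop(columns=["report_date"])
        pieces.append(m)

    cp = pd.concat(pieces, ignore_index=True, sort=False)
    cp = cp.sort_values(["row_id", "offset"], kind="stable")
    cp = cp.drop_duplicates(["row_id", "offset"], keep="last")

    if split_days:
        grids = []
        tmax = int(rows["time_days"].max())
        for k in range(split_days, tmax, split_days):
            g = rows.loc[rows["time_days"] > k, ["row_id"]].copy()
            g["offset"] = float(k)
            grids.append(g)
        if grids:
            grid = pd.concat(grids, ignore_index=True)
            grid["_grid"] = True
            cp["_grid"] = False
            cp = pd.concat([cp, grid], ignore_index=True, sort=False)
            cp = cp.sort_values(["row_id", "offset", "_grid"], kind="stable")
            cp = cp.drop_duplicates(["row_id", "offset"], keep="first")
            fill_cols = ["patient_id", "cs_date", "country", "stratum", "time_days", "event",
                         "censor_cause", "creatinine", "bilirubin", "inr", "dialysis"]
            cp[fill_cols] = cp.groupby("row_id")[fill_cols].ffill()
            cp = cp.drop(columns=["_grid"])

    cp = cp.reset_index(drop=True)
    cp["t_start"] = cp["offset"]
    nxt = cp["offset"].shift(-1)
    last = cp["row_id"] != cp["row_id"].shift(-1)
    cp["t_stop"] = np.where(last, cp["time_days"], nxt)
    cp = cp[cp["t_stop"] > cp["t_start"]].reset_index(drop=True)
    last = (cp["row_id"] != cp["row_id"].shift(-1)).to_numpy()
    cp["event"] = cp["event"].astype(bool) & last
    cp["cens_transplant"] = (cp["censor_cause"] == "transplant") & last
    cp["cens_delisting"] = (cp["censor_cause"] == "delisting") & last
    cp["dialysis"] = cp["dialysis"].astype(bool)
    cp = censoring_covariate_columns(cp.drop(columns=["offset"]))
    # the cz_* covariates above are time-varying (censoring models need the
    # updated reports); the analysis biomarkers are frozen back to their
    # cross-section values so downstream mortality fits adjust only for
    # information available at the cross-section
    raw = ["creatinine", "bilirubin", "inr", "dialysis"]
    cp[raw] = cp.groupby("row_id")[raw].transform("first")
    return cp


def _marginal_cumhaz(cp: pd.DataFrame, event_col: str, strata_col: str) -> dict:
    """Stratum-wise Nelson–Aalen cumulative hazard of one censoring cause."""
    out = {}
    tmax = int(cp["t_stop"].max())
    for s, grp in cp.groupby(strata_col, sort=True):
        t0 = grp["t_start"].to_numpy(dtype=int)
        t1 = grp["t_stop"].to_numpy(dtype=int)
        d = grp[event_col].to_numpy(dtype=bool)
        atrisk = np.zeros(tmax + 2)
        np.add.at(atrisk, t0 + 1, 1.0)
        np.add.at(atrisk, t1 + 1, -1.0)
        atrisk = np.cumsum(atrisk)
        ev = np.zeros(tmax + 2)
        np.add.at(ev, t1[d], 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            inc = np.where(atrisk[: tmax + 1] > 0, ev[: tmax + 1] / atrisk[: tmax + 1], 0.0)
        out[s] = np.cumsum(inc)
    return out


def fit_censoring_model(
    cp: pd.DataFrame,
    cause: str,
    covariates=CENSORING_COVARIATES,
    strata_col: str = "country",
) -> CensoringModel:
    """Fit the cause-specific censoring model on counting-process data.

    ``cause`` is ``"transplant"`` or ``"delisting"``; the other cause and
    death act as ordinary censoring.  An empty covariate list yields the
    covariate-free (marginal) model.
    """
    event_col = f"cens_{cause}"
    if event_col not in cp:
        raise ValueError(f"unknown censoring cause {cause!r}")
    if not cp[event_col].any():
        raise ValueError(f"cannot estimate weights: no {cause} events")
    covariates = list(covariates)
    result = None
    # rare causes can leave a covariate (typically dialysis) constant over the
    # event risk sets; degrade gracefully: drop it, then fall back to the
    # covariate-free model
    attempts = [covariates]
    if "cz_dialysis" in covariates:
        attempts.append([c for c in covariates if c != "cz_dialysis"])
    attempts.append([])
    for cand in attempts:
        if not cand:
            covariates = []
            break
        try:
            result = fit_cox(
                cp,
                cand,
                start_col="t_start",
                stop_col="t_stop",
                event_col=event_col,
                strata_col=strata_col,
            )
            covariates = cand
            break
        except ValueError:
            result = None
            continue
    marginal = _marginal_cumhaz(cp, event_col, strata_col)
    return CensoringModel(
        cause=cause,
        covariates=covariates,
        strata_col=strata_col,
        result=result,
        marginal_cumhaz=marginal,
    )


def compute_weights(
    cp: pd.DataFrame,
    model_T: CensoringModel,
    model_D: CensoringModel,
    stabilize: bool = True,
    truncation_quantile: float | None = 0.99,
) -> pd.DataFrame:
    """Attach joint IPCW weights to the counting-process intervals.

    Each interval ``(t_start, t_stop]`` receives the weight evaluated at its
    end: ``1 / (S_T(t_stop) * S_D(t_stop))`` given the row's covariate
    history, times the marginal survival product when ``stabilize``.  Weights
    are capped at the ``truncation_quantile`` of the weight distribution.
    """
    cp = cp.copy()
    log_w = np.zeros(len(cp))
    for model, tag in ((model_T, "T"), (model_D, "D")):
        inc = model.cumhaz_increment(cp)
        H = _groupwise_cumsum(inc, cp["row_id"].to_numpy())
        if not np.all(np.isfinite(H)):
            bad = int(np.argmax(~np.isfinite(H)))
            raise ValueError(f"censoring survival underflow (S_{tag} = 0) at interval row {bad}")
        cp[f"surv_{tag}"] = np.exp(-H)
        log_w = log_w + H
        if stabilize:
            Hm = _groupwise_cumsum(model.marginal_increment(cp), cp["row_id"].to_numpy())
            cp[f"marg_surv_{tag}"] = np.exp(-Hm)
            log_w = log_w - Hm

    # exp of the net log-weight: exactly 1.0 when model and stabilizer coincide
    w = np.exp(log_w)
    if truncation_quantile is not None:
        w = np.minimum(w, np.quantile(w, truncation_quantile))
    cp["weight"] = w
    return cp


def _groupwise_cumsum(vals: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Cumulative sum restarting whenever ``group`` changes (assumed contiguous).

    Requires ``vals >= 0`` (cumulative-hazard increments), which makes the
    running total monotone so each group's starting offset can be
    forward-filled with a running maximum.
    """
    cs = np.cumsum(vals)
    first = np.ones(len(vals), dtype=bool)
    first[1:] = group[1:] != group[:-1]
    offset = np.maximum.accumulate(np.where(first, cs - vals, -np.inf))
    return cs - offset
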