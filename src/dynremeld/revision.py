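"""MELD revision: weighted stratified 90-day mortality models and score derivation.

The central object is :class:`MortalityModel`, a statsmodels-style model
built from an analysis dataset (from-registration or from-cross-section
rows, optionally expanded to IPCW-weighted intervals).  ``fit()`` returns a
:class:`MortalityResults` carrying coefficients, standard errors, the
covariance matrix, the partial log-likelihood and the likelihood-ratio test
against the stated null — the offset-only model when a reference score
enters as an offset, the empty model otherwise.

The adjustment set follows allocation practice: log capped creatinine with
creatinine set to 1.0 for patients on biweekly dialysis (so the creatinine
term carries no information for them), log capped bilirubin, log capped
INR, and a dialysis indicator.

On top of the fit sit the score-derivation steps: likelihood-based cap
optimization (coordinate-wise sweeps), quantile matching of the linear
predictor to a reference score scale, and assembly of a
:class:`~dynremeld.scores.ScoreDefinition` with coefficients rounded to the
conventional two decimals and dialysis handled by substituting creatinine
at its upper cap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFitResult, fit_cox
from .scores import ScoreDefinition, apply_caps, compute_score_frame

__all__ = [
    "MORTALITY_COVARIATES",
    "MortalityModel",
    "MortalityResults",
    "CapSearchResult",
    "mortality_design",
    "fit_mortality_model",
    "lr_test",
    "optimize_caps",
    "quantile_match",
    "derive_score",
    "dialysis_equivalent_creatinine",
]

MORTALITY_COVARIATES = ["log_creatinine", "log_bilirubin", "log_inr", "dialysis_f"]
DEFAULT_QUANTILE_GRID = np.arange(1, 100)


def mortality_design(
    rows: pd.DataFrame,
    caps: dict | None = None,
    dialysis_as_covariate: bool = True,
    offset_score: ScoreDefinition | None = None,
    offset_scale: float = 1.0,
) -> pd.DataFrame:
    """Attach the mortality-model design columns to an analysis frame.

    ``caps`` maps biomarker name to (lower, upper); ``None`` leaves the
    biomarker uncapped.  Creatinine is set to 1.0 for dialysis patients
    before capping.  When ``offset_score`` is given, its points are divided
    by ``offset_scale`` to form the fixed log-hazard offset column.
    """
    rows = rows.copy()
    caps = caps or {}
    dial = rows["dialysis"].astype(bool).to_numpy()
    crea = np.where(dial, 1.0, rows["creatinine"].astype(float))
    vals = {
        "log_creatinine": apply_caps(crea, caps.get("creatinine", (0.0, np.inf))),
        "log_bilirubin": apply_caps(rows["bilirubin"].astype(float), caps.get("bilirubin", (0.0, np.inf))),
        "log_inr": apply_caps(rows["inr"].astype(float), caps.get("inr", (0.0, np.inf))),
    }
    for c, v in vals.items():
        rows[c] = np.log(v)
    if dialysis_as_covariate:
        rows["dialysis_f"] = dial.astype(float)
    if offset_score is not None:
        rows["offset_lp"] = compute_score_frame(offset_score, rows) / float(offset_scale)
    return rows


@dataclass
class MortalityResults:
    """Results wrapper: fitted coefficients plus derivation helpers."""

    fit: CoxFitResult
    covariates: list
    caps: dict | None
    offset_score_name: str | None = None
    offset_scale: float | None = None

    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def standard_errors(self) -> pd.Series:
        return self.fit.standard_errors

    @property
    def covariance(self) -> pd.DataFrame:
        return self.fit.covariance

    @property
    def log_likelihood(self) -> float:
        return self.fit.log_likelihood

    @property
    def lr_statistic(self) -> float:
        return self.fit.lr_statistic

    @property
    def lr_df(self) -> int:
        return self.fit.df

    def linear_predictor(self, design: pd.DataFrame) -> np.ndarray:
        X = design[self.covariates].to_numpy(dtype=float)
        return X @ self.params.to_numpy()

    def summary(self) -> pd.DataFrame:
        tab = self.fit.summary()
        tab.attrs["offset"] = self.offset_score_name or "none"
        tab.attrs["caps"] = self.caps
        return tab


class MortalityModel:
    """90-day time-stopped Cox model for waitlist mortality.

    Parameters
    ----------
    rows : DataFrame
        Analysis rows (one per observation, or IPCW interval rows carrying
        ``t_start``/``t_stop``/``weight``) with raw biomarkers, ``time_days``,
        ``event`` and a ``stratum`` column.
    caps : dict or None
        Per-biomarker (lower, upper) bounds; None fits uncapped logs.
    offset_score, offset_scale
        Optional reference score entering as a fixed offset; points are
        divided by ``offset_scale`` to reach the log-hazard scale.  With
        ``offset_scale=None`` the scale is estimated by quantile-matching
        the reference score against the linear predictor of the offset-free
        fit on the same rows.
    """

    def __init__(
        self,
        rows: pd.DataFrame,
        caps: dict | None = None,
        dialysis_as_covariate: bool = True,
        offset_score: ScoreDefinition | None = None,
        offset_scale: float | None = 1.0,
        stratify: bool = True,
        weighted: bool | None = None,
        quantile_grid=DEFAULT_QUANTILE_GRID,
    ) -> None:
        self.rows = rows
        self.caps = caps
        self.dialysis_as_covariate = dialysis_as_covariate
        self.offset_score = offset_score
        self.offset_scale = offset_scale
        self.stratify = stratify
        self.quantile_grid = quantile_grid
        if weighted is None:
            weighted = "weight" in rows.columns
        self.weighted = weighted
        self.covariates = list(MORTALITY_COVARIATES if dialysis_as_covariate else MORTALITY_COVARIATES[:3])

    @classmethod
    def from_dataframe(cls, rows, **kwargs) -> "MortalityModel":
        return cls(rows, **kwargs)

    def _fit_kwargs(self):
        kw = dict(event_col="event")
        if "t_start" in self.rows.columns and "t_stop" in self.rows.columns:
            kw.update(start_col="t_start", stop_col="t_stop")
        else:
            kw.update(stop_col="time_days")
        if self.weighted:
            kw.update(weight_col="weight")
        if self.stratify:
            kw.update(strata_col="stratum")
        if "patient_id" in self.rows.columns:
            # repeated cross-section rows of one patient are correlated
            kw.update(cluster_col="patient_id")
        return kw

    def fit(self) -> MortalityResults:
        if not len(self.rows):
            raise ValueError("no rows to fit")
        offset_scale = self.offset_scale
        if self.offset_score is not None and offset_scale is None:
            base = mortality_design(self.rows, self.caps, self.dialysis_as_covariate)
            free = fit_cox(base, self.covariates, **self._fit_kwargs())
            lp = base[self.covariates].to_numpy(dtype=float) @ free.params.to_numpy()
            ref = compute_score_frame(self.offset_score, base)
            offset_scale, _ = quantile_match(lp, ref, self.quantile_grid)
        design = mortality_design(
            self.rows, self.caps, self.dialysis_as_covariate, self.offset_score,
            offset_scale if self.offset_score is not None else 1.0,
        )
        kw = self._fit_kwargs()
        if self.offset_score is not None:
            kw.update(offset_col="offset_lp")
        fit = fit_cox(design, self.covariates, **kw)
        return MortalityResults(
            fit=fit,
            covariates=self.covariates,
            caps=self.caps,
            offset_score_name=self.offset_score.name if self.offset_score is not None else None,
            offset_scale=offset_scale if self.offset_score is not None else None,
        )


def fit_mortality_model(
    rows: pd.DataFrame,
    caps: dict | None = None,
    dialysis_as_covariate: bool = True,
    offset_score: ScoreDefinition | None = None,
    offset_scale: float | None = 1.0,
    stratify_by_cross_section: bool = True,
    weighted: bool | None = None,
) -> MortalityResults:
    """Functional facade over :class:`MortalityModel` (build + fit)."""
    return MortalityModel(
        rows,
        caps=caps,
        dialysis_as_covariate=dialysis_as_covariate,
        offset_score=offset_score,
        offset_scale=offset_scale,
        stratify=stratify_by_cross_section,
        weighted=weighted,
    ).fit()


def lr_test(statistic_or_full, null_loglik=None, df=None):
    """Likelihood-ratio test of nested partial likelihoods.

    Either pass a fitted results object plus the null log-likelihood, or
    the statistic directly (``lr_test(4.1, df=3)``).  Returns
    ``(statistic, p_value)`` from the chi-square upper tail.
    """
    if hasattr(statistic_or_full, "log_likelihood"):
        if null_loglik is None or df is None:
            raise ValueError("need null_loglik and df with a results object")
        statistic = 2.0 * (statistic_or_full.log_likelihood - null_loglik)
    else:
        statistic = float(statistic_or_full)
        if df is None:
            raise ValueError("df required")
    if statistic < -1e-6:
        raise ValueError("negative LR statistic: models not nested or not converged")
    statistic = max(statistic, 0.0)
    return statistic, float(stats.chi2.sf(statistic, df))


@dataclass
class CapSearchResult:
    """Outcome of the coordinate-wise likelihood search for biomarker bounds."""

    caps: dict
    log_likelihood: float
    profile: pd.DataFrame = field(repr=False, default=None)
    n_sweeps: int = 0


def optimize_caps(
    rows: pd.DataFrame,
    search_grid: dict,
    sweep_order=("creatinine", "bilirubin", "inr"),
    max_sweeps: int = 3,
    **fit_kwargs,
) -> CapSearchResult:
    """Likelihood-based biomarker bounds.

    ``search_grid[biomarker] = (candidate_lowers, candidate_uppers)``.  Each
    biomarker's (lower, upper) pair is optimized in turn holding the others
    fixed, refitting the multivariable model at every candidate; sweeps
    repeat until no cap changes (at most ``max_sweeps``).  Likelihood ties
    break towards wider bounds.
    """
    current = {
        b: (min(search_grid[b][0]), max(search_grid[b][1])) for b in sweep_order
    }
    records = []
    best_ll = None
    n_sweeps = 0
    for sweep in range(1, max_sweeps + 1):
        n_sweeps = sweep
        changed = False
        for b in sweep_order:
            lows, highs = search_grid[b]
            best = None
            for lo, hi in itertools.product(lows, highs):
                if not lo < hi:
                    continue
                caps = dict(current)
                caps[b] = (float(lo), float(hi))
                ll = fit_mortality_model(rows, caps=caps, **fit_kwargs).log_likelihood
                records.append({"sweep": sweep, "biomarker": b, "lower": lo, "upper": hi, "loglik": ll})
                key = (ll, hi - lo, -lo)
                if best is None or key > best[0]:
                    best = (key, (float(lo), float(hi)))
            if best[1] != current[b]:
                changed = True
                current[b] = best[1]
            best_ll = best[0][0]
        if not changed:
            break
    profile = pd.DataFrame.from_records(records)
    best_ll = fit_mortality_model(rows, caps=current, **fit_kwargs).log_likelihood
    return CapSearchResult(caps=current, log_likelihood=best_ll, profile=profile, n_sweeps=n_sweeps)


def quantile_match(
    linear_predictor, reference_scores, quantile_grid=DEFAULT_QUANTILE_GRID
) -> tuple[float, float]:
    """Affine map from the linear-predictor scale to the reference-score scale.

    Least-squares fit of reference-score quantiles on linear-predictor
    quantiles over ``quantile_grid`` (percentiles).  Returns ``(a, b)`` with
    ``score ~ a * lp + b``.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    ref = np.asarray(reference_scores, dtype=float)
    if np.ptp(lp) == 0:
        raise ValueError("linear predictor has zero variance; quantile match undefined")
    qx = np.percentile(lp, quantile_grid)
    qy = np.percentile(ref, quantile_grid)
    a, b = np.polyfit(qx, qy, 1)
    return float(a), float(b)


def dialysis_equivalent_creatinine(results: MortalityResults) -> float:
    """Creatinine level granting the same priority as biweekly dialysis.

    ``exp(beta_dialysis / beta_creatinine)`` — used to justify replacing the
    dialysis term by a creatinine substitution at the upper cap.
    """
    p = results.params
    return float(np.exp(p["dialysis_f"] / p["log_creatinine"]))


def derive_score(
    results: MortalityResults,
    scale: float,
    shift: float,
    caps: dict,
    name: str = "RevisedMELD",
) -> ScoreDefinition:
    """Turn a fitted mortality model into a MELD-style score definition.

    Coefficients are ``scale * beta`` rounded to two decimals, the intercept
    is ``shift`` rounded to two decimals, and dialysis is handled by
    substituting creatinine at its upper cap (sensible when the cap is close
    to the dialysis-equivalent creatinine).
    """
    p = results.params
    return ScoreDefinition(
        name=name,
        intercept=round(float(shift), 2),
        coef_crea=round(scale * float(p["log_creatinine"]), 2),
        coef_bili=round(scale * float(p["log_bilirubin"]), 2),
        coef_inr=round(scale * float(p["log_inr"]), 2),
        bounds={b: tuple(caps[b]) for b in ("creatinine", "bilirubin", "inr")},
        dialysis_creatinine=float(caps["creatinine"][1]),
    )
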