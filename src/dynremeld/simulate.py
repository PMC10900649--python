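"""Synthetic waitlist-registry generator with known ground truth.

The generator reproduces the statistical *structure* the cross-section/IPCW
analysis relies on, not the marginal distributions of any real registry:

* latent log-biomarkers follow a daily random walk with drift, with a
  progressor/stable mixture (progressors drift towards worse values);
* biomarker *reports* are emitted at registration, whenever the current
  report's age exceeds the recertification limit for the patient's current
  (reported) UNOS-MELD band — sicker patients recertify more often — and
  occasionally voluntarily;
* the daily death hazard is ``baseline * exp(beta . x_reported)`` where the
  covariate vector uses the mortality-model parameterisation (log creatinine
  zeroed under dialysis, log bilirubin, log INR, dialysis indicator);
* transplant and delisting hazards are either constant ("independent"
  scenario A) or log-linear in the current *reported* UNOS-MELD score
  ("score_dependent" scenario B), which makes censoring informative while
  keeping an IPCW censoring model on reported values correctly specified;
* competing events within a day are resolved by each cause's exponential
  waiting time under that day's constant hazards (ties: death > transplant
  > delisting);
* delisted patients carry a post-delisting death process for 90 days with
  hazards frozen at delisting;
* a configurable fraction of patients receives one NT interval.

Everything is reproducible from ``config.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .registry import Registry
from .scores import UNOS_MELD, compute_score

__all__ = ["SimulationConfig", "GroundTruth", "simulate_registry", "default_scenarios"]

# recertification: (upper band edge of the reported UNOS-MELD score, max report age in days)
DEFAULT_RECERT = ((10, 365), (18, 90), (25, 30), (math.inf, 7))


@dataclass
class SimulationConfig:
    """Ground-truth parameters and study-window layout for one scenario."""

    n_patients: int = 3000
    window_start: str = "2014-01-01"
    window_end: str = "2015-12-31"
    # (country code, number of centers, patient share)
    countries: tuple = (("DE", 6, 0.60), ("BE", 3, 0.25), ("HR", 1, 0.15))
    # death log-hazard ratios: log crea (zeroed on dialysis), log bili, log INR, dialysis
    true_beta: tuple = (2.15, 0.97, 2.22, 1.86)
    baseline_death_hazard: float = 9e-5  # events/day at covariate zero
    transplant_hazard_model: str = "score_dependent"  # or "independent"
    base_transplant_hazard: float = 1.5e-3
    gamma_tx: float = 0.12  # log-HR per reported UNOS-MELD point above score_ref
    delisting_hazard_model: str = "score_dependent"
    base_delisting_hazard: float = 3e-4
    gamma_dl: float = 0.08
    score_ref: float = 15.0
    # optional saturation: the score entering the transplant/delisting hazards
    # is capped here (allocation intensity plateaus at the top of the list,
    # which also keeps censoring probabilities bounded away from one); the
    # default leaves the dependence purely log-linear
    censoring_score_cap: float = math.inf
    # biomarker process (log scale): initial mean/sd, progressor drift/day, volatility/day
    init_mean: tuple = (0.05, 0.85, 0.25)  # log crea, log bili, log INR
    init_sd: tuple = (0.30, 0.80, 0.22)
    # drift heterogeneity: progressors drift by progressor_drift, the rest not
    # at all.  The default is a *homogeneous* drift (fraction 1.0): a latent
    # progressor class acts as a shared frailty that makes fixed-covariate
    # hazard models inconsistent, which would confound the censoring-bias
    # comparisons the default scenarios exist for.
    progressor_fraction: float = 1.0
    progressor_drift: tuple = (0.0008, 0.0022, 0.0008)
    volatility: tuple = (0.012, 0.022, 0.009)
    dialysis_onset_base: float = 5e-5  # daily onset hazard at log crea = 0
    dialysis_onset_slope: float = 1.8
    init_dialysis_base: float = 0.09  # listing-time dialysis probability at log crea = 0
    recert_schedule: tuple = DEFAULT_RECERT
    voluntary_report_rate: float = 0.01  # per day
    nt_fraction: float = 0.08
    nt_mean_duration: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        for h in (
            self.baseline_death_hazard,
            self.base_transplant_hazard,
            self.base_delisting_hazard,
        ):
            if h < 0:
                raise ValueError("hazards must be non-negative")
        if not 0 <= self.progressor_fraction <= 1:
            raise ValueError("progressor_fraction must lie in [0, 1]")
        if self.window_end is None:
            if (
                self.baseline_death_hazard == 0
                and self.base_transplant_hazard == 0
                and self.base_delisting_hazard == 0
            ):
                raise ValueError("no termination: zero hazards and no data cutoff")
            raise ValueError("window_end (data cutoff) is required")
        if pd.Timestamp(self.window_end) <= pd.Timestamp(self.window_start):
            raise ValueError("window_end must be after window_start")


@dataclass
class GroundTruth:
    """What the generator actually used — for parameter-recovery tests."""

    true_beta: dict
    gamma_tx: float
    gamma_dl: float
    baseline_death_hazard: float
    base_transplant_hazard: float
    base_delisting_hazard: float
    score_ref: float
    progressor: np.ndarray = field(repr=False, default=None)
    exit_day: np.ndarray = field(repr=False, default=None)
    exit_cause: np.ndarray = field(repr=False, default=None)


def _recert_limit(schedule, scores):
    limits = np.empty(len(scores))
    limits.fill(schedule[-1][1])
    prev = -math.inf
    for edge, lim in schedule:
        limits[(scores > prev) & (scores <= edge)] = lim
        prev = edge
    return limits


def simulate_registry(config: SimulationConfig) -> tuple[Registry, GroundTruth]:
    """Simulate one registry; fully reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    epoch = pd.Timestamp(config.window_start)
    W = int((pd.Timestamp(config.window_end) - epoch).days)
    b_crea, b_bili, b_inr, b_dial = config.true_beta

    reg_day = rng.integers(0, W, size=n)
    progressor = rng.random(n) < config.progressor_fraction
    drift = np.where(progressor[:, None], np.asarray(config.progressor_drift), 0.0)
    vol = np.asarray(config.volatility)
    init = rng.normal(np.asarray(config.init_mean), np.asarray(config.init_sd), size=(n, 3))

    latent = np.zeros((n, 3))
    reported = np.zeros((n, 3))
    dial = np.zeros(n, dtype=bool)
    dial_rep = np.zeros(n, dtype=bool)
    rep_day = np.full(n, -(10**6))
    exited = np.zeros(n, dtype=bool)
    registered = np.zeros(n, dtype=bool)
    exit_day = np.full(n, -1)
    exit_cause = np.zeros(n, dtype=int)  # 0 none, 1 death, 2 transplant, 3 delisting
    death_hazard_now = np.zeros(n)

    rep_pid, rep_t, rep_vals, rep_dial = [], [], [], []

    def emit_reports(idx, t):
        # reported values are rounded to registry precision (2 decimals) and
        # the rounded values drive all downstream hazards, so the emitted
        # tables fully determine the event processes
        vals = np.maximum(np.round(np.exp(latent[idx]), 2), 0.01)
        reported[idx] = np.log(vals)
        dial_rep[idx] = dial[idx]
        rep_day[idx] = t
        rep_pid.append(idx.copy())
        rep_t.append(np.full(len(idx), t))
        rep_vals.append(vals)
        rep_dial.append(dial[idx].copy())

    for t in range(W):
        newly = reg_day == t
        if newly.any():
            latent[newly] = init[newly]
            registered[newly] = True
            p0 = np.clip(
                config.init_dialysis_base
                * np.exp(config.dialysis_onset_slope * latent[newly, 0]),
                0,
                1,
            )
            dial[newly] = rng.random(newly.sum()) < p0
        active = registered & ~exited
        if not active.any():
            continue
        idx = np.flatnonzero(active)
        old = idx[reg_day[idx] < t]
        if len(old):
            latent[old] += drift[old] + vol * rng.normal(size=(len(old), 3))
            onset = rng.random(len(old)) < -np.expm1(
                -config.dialysis_onset_base
                * np.exp(config.dialysis_onset_slope * latent[old, 0])
            )
            dial[old[onset]] = True

        # reporting: mandatory at listing, recertification by band, voluntary
        unos_rep = compute_score(
            UNOS_MELD,
            np.exp(reported[idx, 0]),
            np.exp(reported[idx, 1]),
            np.exp(reported[idx, 2]),
            dial_rep[idx],
        )
        limit = _recert_limit(config.recert_schedule, np.atleast_1d(unos_rep))
        need = (
            (reg_day[idx] == t)
            | (t - rep_day[idx] >= limit)
            | (rng.random(len(idx)) < config.voluntary_report_rate)
        )
        if need.any():
            emit_reports(idx[need], t)

        # daily hazards driven by the *reported* values
        xc = np.where(dial_rep[idx], 0.0, reported[idx, 0])
        h_death = config.baseline_death_hazard * np.exp(
            b_crea * xc
            + b_bili * reported[idx, 1]
            + b_inr * reported[idx, 2]
            + b_dial * dial_rep[idx]
        )
        death_hazard_now[idx] = h_death
        unos_now = compute_score(
            UNOS_MELD,
            np.exp(reported[idx, 0]),
            np.exp(reported[idx, 1]),
            np.exp(reported[idx, 2]),
            dial_rep[idx],
        )
        unos_now = np.minimum(np.atleast_1d(unos_now), config.censoring_score_cap)
        if config.transplant_hazard_model == "score_dependent":
            h_tx = config.base_transplant_hazard * np.exp(
                config.gamma_tx * (unos_now - config.score_ref)
            )
        else:
            h_tx = np.full(len(idx), config.base_transplant_hazard)
        if config.delisting_hazard_model == "score_dependent":
            h_dl = config.base_delisting_hazard * np.exp(
                config.gamma_dl * (unos_now - config.score_ref)
            )
        else:
            h_dl = np.full(len(idx), config.base_delisting_hazard)

        # competing exponential waiting times within the day; earliest cause wins,
        # ties (measure zero) broken death > transplant > delisting by argmin order
        with np.errstate(divide="ignore"):
            waits = np.stack(
                [
                    rng.exponential(size=len(idx)) / np.maximum(h_death, 1e-300),
                    rng.exponential(size=len(idx)) / np.maximum(h_tx, 1e-300),
                    rng.exponential(size=len(idx)) / np.maximum(h_dl, 1e-300),
                ]
            )
        waits[0, h_death <= 0] = np.inf
        waits[1, h_tx <= 0] = np.inf
        waits[2, h_dl <= 0] = np.inf
        first = waits.min(axis=0)
        hit = first < 1.0
        if hit.any():
            who = idx[hit]
            cause = waits[:, hit].argmin(axis=0) + 1
            exited[who] = True
            exit_day[who] = t
            exit_cause[who] = cause

    # post-delisting death: 90 further days with the hazard frozen at delisting
    delisted = exit_cause == 3
    pdd_day = np.full(n, -1)
    followup = np.full(n, -1)
    if delisted.any():
        who = np.flatnonzero(delisted)
        wait = rng.exponential(size=len(who)) / np.maximum(death_hazard_now[who], 1e-300)
        died = wait <= 90
        pdd_day[who[died]] = exit_day[who[died]] + np.ceil(wait[died]).astype(int)
        followup[who] = 90

    # assemble tables ------------------------------------------------------
    pid = np.array([f"P{i:06d}" for i in range(n)])
    shares = np.array([c[2] for c in config.countries], dtype=float)
    shares = shares / shares.sum()
    country_idx = rng.choice(len(config.countries), size=n, p=shares)
    country = np.array([config.countries[k][0] for k in country_idx])
    center = np.array(
        [
            f"{config.countries[k][0]}{rng.integers(config.countries[k][1]):02d}"
            for k in country_idx
        ]
    )

    reason = np.select(
        [exit_cause == 1, exit_cause == 2, exit_cause == 3],
        ["death", "transplant", "delisting"],
        default="censored",
    )
    to_date = lambda days: epoch + pd.to_timedelta(days, unit="D")
    regs = pd.DataFrame(
        {
            "patient_id": pid,
            "center_id": center,
            "country": country,
            "registration_date": to_date(reg_day),
            "exit_date": to_date(np.where(exit_cause > 0, exit_day, -1)).where(exit_cause > 0),
            "exit_reason": reason,
            "post_delisting_death_date": to_date(np.where(pdd_day >= 0, pdd_day, -1)).where(
                pdd_day >= 0
            ),
            "post_delisting_followup_days": pd.array(
                np.where(followup >= 0, followup, -1), dtype="Int64"
            ),
        }
    )
    regs.loc[regs["post_delisting_followup_days"] < 0, "post_delisting_followup_days"] = pd.NA

    if rep_pid:
        rp = np.concatenate(rep_pid)
        vals = np.concatenate(rep_vals)
        reports = pd.DataFrame(
            {
                "patient_id": pid[rp],
                "report_date": to_date(np.concatenate(rep_t)),
                "creatinine": vals[:, 0],
                "bilirubin": vals[:, 1],
                "inr": vals[:, 2],
                "dialysis": np.concatenate(rep_dial),
            }
        ).sort_values(["patient_id", "report_date"], kind="stable").reset_index(drop=True)
    else:
        reports = pd.DataFrame(
            columns=["patient_id", "report_date", "creatinine", "bilirubin", "inr", "dialysis"]
        )

    # NT intervals for a random fraction of sufficiently long stayers
    exit_eff = np.where(exit_cause > 0, exit_day, W)
    stay = exit_eff - reg_day
    eligible = np.flatnonzero(stay >= 14)
    n_nt = int(round(config.nt_fraction * n))
    nt_rows = []
    if n_nt and len(eligible):
        chosen = rng.choice(eligible, size=min(n_nt, len(eligible)), replace=False)
        starts = reg_day[chosen] + 1 + rng.integers(0, np.maximum(stay[chosen] - 7, 1))
        durations = 1 + rng.geometric(1.0 / config.nt_mean_duration, size=len(chosen))
        for i, s, d in zip(chosen, starts, durations):
            nt_rows.append((pid[i], s, min(s + d, exit_eff[i])))
    statuses = pd.DataFrame(
        {
            "patient_id": [r[0] for r in nt_rows],
            "start_date": to_date(np.array([r[1] for r in nt_rows], dtype=int))
            if nt_rows
            else pd.Series([], dtype="datetime64[ns]"),
            "end_date": to_date(np.array([r[2] for r in nt_rows], dtype=int))
            if nt_rows
            else pd.Series([], dtype="datetime64[ns]"),
            "status": "NT",
        }
    )

    registry = Registry(regs, reports, statuses, cutoff_date=pd.Timestamp(config.window_end))
    truth = GroundTruth(
        true_beta={
            "log_creatinine": b_crea,
            "log_bilirubin": b_bili,
            "log_inr": b_inr,
            "dialysis": b_dial,
        },
        gamma_tx=config.gamma_tx if config.transplant_hazard_model == "score_dependent" else 0.0,
        gamma_dl=config.gamma_dl if config.delisting_hazard_model == "score_dependent" else 0.0,
        baseline_death_hazard=config.baseline_death_hazard,
        base_transplant_hazard=config.base_transplant_hazard,
        base_delisting_hazard=config.base_delisting_hazard,
        score_ref=config.score_ref,
        progressor=progressor,
        exit_day=exit_day,
        exit_cause=exit_cause,
    )
    return registry, truth


def default_scenarios() -> dict[str, SimulationConfig]:
    """The two study scenarios.

    ``A_independent`` — transplant and delisting hazards constant, so
    censoring is independent and the naive (unweighted) fit is consistent.
    ``B_informative`` — both censoring hazards increase with the current
    reported UNOS-MELD score, so naive fitting is biased and IPCW is needed.
    Both share ``true_beta`` to enable paired bias comparisons.
    """
    a = SimulationConfig(
        transplant_hazard_model="independent",
        delisting_hazard_model="independent",
        gamma_tx=0.0,
        gamma_dl=0.0,
    )
    b = SimulationConfig()
    return {"A_independent": a, "B_informative": b}
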