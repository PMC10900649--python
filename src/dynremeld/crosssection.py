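"""Construction of the two survival-analysis datasets.

The *from-registration* design follows each listing episode from its own
registration date; the *from-cross-section* design samples every actively
listed, transplantable patient at pre-specified calendar dates (weekly by
default) and follows each sampled patient forward, adjusting for the last
biomarker report on or before the sampling date.  Patients waiting across
several cross-sections contribute several correlated rows, which is why
downstream resampling is clustered on ``patient_id``.

Outcomes are 90-day time-stopped: death on the waitlist within the horizon
is an event; a delisted patient who dies within 90 days of delisting is
counted as having died at waitlist exit; transplantation and (other)
delisting censor follow-up at exit; reaching the horizon or the
administrative data cutoff censors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "cross_section_dates",
    "active_at",
    "last_report_before",
    "encode_outcome",
    "build_cross_section_dataset",
    "build_from_registration_dataset",
    "HORIZON_DAYS",
]

HORIZON_DAYS = 90

# censor_cause codes used in the long-format dataset
CAUSES = {0: None, 1: "transplant", 2: "delisting", 3: "administrative", 4: "horizon"}
CAUSE_CODES = {v: k for k, v in CAUSES.items()}


def cross_section_dates(start, end, spacing_days: int = 7) -> pd.DatetimeIndex:
    """Arithmetic grid of calendar cross-section dates from start to end."""
    if spacing_days <= 0:
        raise ValueError("spacing_days must be positive")
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start > end:
        raise ValueError("start must be on or before end")
    return pd.date_range(start, end, freq=f"{spacing_days}D")


def _exit_effective(registration, cutoff):
    exit_date = registration.get("exit_date") if isinstance(registration, dict) else registration["exit_date"]
    if pd.isna(exit_date):
        if cutoff is None:
            raise ValueError("registration without exit_date requires a cutoff date")
        return pd.Timestamp(cutoff)
    return pd.Timestamp(exit_date)


def active_at(registration, statuses: pd.DataFrame, date, cutoff=None) -> bool:
    """Was this registration active (listed, transplantable) on ``date``?

    Active means ``registration_date <= date < exit`` (exit falling back to
    the cutoff when absent) and ``date`` not inside any NT interval
    ``[start_date, end_date)`` (an absent end date is open-ended).
    """
    date = pd.Timestamp(date)
    reg_date = pd.Timestamp(registration["registration_date"])
    if not (reg_date <= date < _exit_effective(registration, cutoff)):
        return False
    if statuses is not None and len(statuses):
        mine = statuses[statuses["patient_id"] == registration["patient_id"]]
        for s in mine.itertuples(index=False):
            end_open = pd.isna(s.end_date)
            if pd.Timestamp(s.start_date) <= date and (end_open or date < pd.Timestamp(s.end_date)):
                return False
    return True


def last_report_before(reports: pd.DataFrame, date, inclusive: bool = True):
    """Last biomarker report dated on (``inclusive``) or strictly before ``date``.

    ``reports`` must be sorted by report date; on same-day ties the
    later-ingested row wins (stable order). Returns None when no report
    qualifies.
    """
    date = pd.Timestamp(date)
    mask = reports["report_date"] <= date if inclusive else reports["report_date"] < date
    sel = reports[mask]
    if not len(sel):
        return None
    return sel.iloc[-1]


def _encode_outcome_arrays(origin_day, exit_day, reason, pdd_day, cutoff_day, horizon):
    """Vectorized outcome encoding on integer day counts.

    reason: object array of exit reasons (None/nan when still listed).
    Returns (time_days, event, cause_code) arrays.
    """
    n = len(origin_day)
    time = np.empty(n, dtype=float)
    event = np.zeros(n, dtype=bool)
    cause = np.zeros(n, dtype=int)

    has_exit = ~np.isnan(exit_day)
    t_exit = exit_day - origin_day
    t_cut = cutoff_day - origin_day if cutoff_day is not None else np.full(n, np.inf)

    # no exit recorded: censor at horizon, or at the cutoff if it comes first
    no_exit = ~has_exit
    time[no_exit] = np.minimum(horizon, t_cut[no_exit] if np.ndim(t_cut) else t_cut)
    cause[no_exit] = np.where(t_cut[no_exit] < horizon, CAUSE_CODES["administrative"], CAUSE_CODES["horizon"])

    # exit beyond horizon: administratively truncated
    late = has_exit & (t_exit > horizon)
    time[late] = horizon
    cause[late] = CAUSE_CODES["horizon"]

    within = has_exit & (t_exit <= horizon)
    time[within] = t_exit[within]
    is_death = within & (reason == "death")
    event[is_death] = True

    is_del = within & (reason == "delisting")
    pdd_within = is_del & ~np.isnan(pdd_day) & (pdd_day - exit_day <= horizon)
    event[pdd_within] = True
    cause[is_del & ~pdd_within] = CAUSE_CODES["delisting"]

    is_tx = within & (reason == "transplant")
    cause[is_tx] = CAUSE_CODES["transplant"]

    is_adm = within & (reason == "censored")
    cause[is_adm] = CAUSE_CODES["administrative"]

    cause[event] = 0
    return time, event, cause


def encode_outcome(registration, origin_date, horizon_days: int = HORIZON_DAYS, cutoff=None):
    """90-day time-stopped outcome from ``origin_date`` for one registration.

    Returns ``(time_days, event, censor_cause)`` with ``censor_cause`` None
    when the event occurred.  A delisting followed by death within 90 days
    of delisting is reclassified as a waitlist death at exit.
    """
    origin = pd.Timestamp(origin_date)
    exit_date = registration["exit_date"]
    pdd = registration.get("post_delisting_death_date", None)
    cutoff_day = None
    if cutoff is not None:
        cutoff_day = float((pd.Timestamp(cutoff) - origin).days)
    time, event, cause = _encode_outcome_arrays(
        np.array([0.0]),
        np.array([np.nan if pd.isna(exit_date) else float((pd.Timestamp(exit_date) - origin).days)]),
        np.array([registration["exit_reason"] if not pd.isna(registration["exit_reason"]) else None], dtype=object),
        np.array([np.nan if pdd is None or pd.isna(pdd) else float((pd.Timestamp(pdd) - origin).days)]),
        np.array([np.inf]) if cutoff_day is None else np.array([cutoff_day]),
        horizon_days,
    )
    return float(time[0]), bool(event[0]), CAUSES[int(cause[0])]


def _day_numbers(series, epoch):
    return (pd.to_datetime(series) - epoch).dt.days.astype(float)


def build_cross_section_dataset(
    registry,
    dates,
    horizon_days: int = HORIZON_DAYS,
    inclusive_report: bool = True,
) -> pd.DataFrame:
    """Long-format analysis dataset: one row per (active registration x cross-section).

    A row requires the registration to be active and transplantable on the
    cross-section date and a biomarker report dated on/before it.  The Cox
    stratum is ``country|cs_date``.
    """
    regs = registry.registrations
    dates = pd.DatetimeIndex(dates)
    cutoff = registry.cutoff_date
    epoch = dates[0]

    date_days = ((dates - epoch).days).to_numpy(dtype=float)
    reg_day = _day_numbers(regs["registration_date"], epoch).to_numpy()
    exit_day = _day_numbers(regs["exit_date"], epoch).to_numpy()
    cutoff_day = float((pd.Timestamp(cutoff) - epoch).days) if cutoff is not None else np.inf
    exit_eff = np.where(np.isnan(exit_day), cutoff_day, exit_day)

    lo = np.searchsorted(date_days, reg_day, side="left")
    hi = np.searchsorted(date_days, exit_eff, side="left")
    hi = np.maximum(hi, lo)
    counts = hi - lo
    reg_idx = np.repeat(np.arange(len(regs)), counts)
    cs_idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)]) if len(regs) else np.array([], int)

    rows = regs.iloc[reg_idx][
        ["patient_id", "center_id", "country", "registration_date", "exit_date",
         "exit_reason", "post_delisting_death_date"]
    ].reset_index(drop=True)
    rows["registration_index"] = reg_idx
    rows["cs_date"] = dates[cs_idx]
    rows["cs_day"] = date_days[cs_idx]

    # drop rows inside an NT interval [start, end)
    statuses = registry.statuses
    if len(statuses):
        st = statuses.copy()
        st["start_day"] = _day_numbers(st["start_date"], epoch)
        st["end_day"] = _day_numbers(st["end_date"], epoch)
        merged = rows[["patient_id", "cs_day"]].reset_index().merge(
            st[["patient_id", "start_day", "end_day"]], on="patient_id", how="inner"
        )
        inside = (merged["cs_day"] >= merged["start_day"]) & (
            merged["end_day"].isna() | (merged["cs_day"] < merged["end_day"])
        )
        drop = merged.loc[inside, "index"].unique()
        rows = rows.drop(index=drop).reset_index(drop=True)

    # last biomarker report on/before the cross-section date
    reports = registry.reports.sort_values("report_date", kind="stable").reset_index(drop=True)
    rows = rows.sort_values("cs_date", kind="stable").reset_index(drop=True)
    rows = pd.merge_asof(
        rows,
        reports.rename(columns={"report_date": "report_date"}),
        left_on="cs_date",
        right_on="report_date",
        by="patient_id",
        direction="backward",
        allow_exact_matches=inclusive_report,
    )
    rows = rows[rows["report_date"].notna()].reset_index(drop=True)
    rows["report_age_days"] = (rows["cs_date"] - rows["report_date"]).dt.days

    origin_day = rows["cs_day"].to_numpy()
    time, event, cause = _encode_outcome_arrays(
        origin_day,
        _day_numbers(rows["exit_date"], epoch).to_numpy(),
        rows["exit_reason"].to_numpy(dtype=object),
        _day_numbers(rows["post_delisting_death_date"], epoch).to_numpy(),
        np.full(len(rows), cutoff_day),
        horizon_days,
    )
    rows["time_days"] = time
    rows["event"] = event
    rows["censor_cause"] = [CAUSES[c] for c in cause]
    rows["stratum"] = rows["country"].astype(str) + "|" + rows["cs_date"].dt.strftime("%Y-%m-%d")
    rows = rows[rows["time_days"] > 0].reset_index(drop=True)
    return rows.drop(columns=["cs_day"])


def build_from_registration_dataset(registry, horizon_days: int = HORIZON_DAYS) -> pd.DataFrame:
    """One row per registration, followed from the registration date.

    Biomarkers are the listing-time report (last report on/before the
    registration date; listing-day reporting is mandatory, so after
    validation this exists for every retained registration).
    """
    regs = registry.registrations.reset_index(drop=True).copy()
    regs["registration_index"] = np.arange(len(regs))
    epoch = pd.Timestamp(regs["registration_date"].min())
    cutoff = registry.cutoff_date
    cutoff_day = float((pd.Timestamp(cutoff) - epoch).days) if cutoff is not None else np.inf

    reports = registry.reports.sort_values("report_date", kind="stable").reset_index(drop=True)
    rows = regs.sort_values("registration_date", kind="stable").reset_index(drop=True)
    rows = pd.merge_asof(
        rows,
        reports,
        left_on="registration_date",
        right_on="report_date",
        by="patient_id",
        direction="backward",
        allow_exact_matches=True,
    )
    n_missing = int(rows["report_date"].isna().sum())
    rows = rows[rows["report_date"].notna()].reset_index(drop=True)
    rows.attrs["n_excluded_no_listing_report"] = n_missing

    rows["cs_date"] = rows["registration_date"]
    rows["report_age_days"] = (rows["cs_date"] - rows["report_date"]).dt.days
    origin_day = _day_numbers(rows["registration_date"], epoch).to_numpy()
    time, event, cause = _encode_outcome_arrays(
        origin_day,
        _day_numbers(rows["exit_date"], epoch).to_numpy(),
        rows["exit_reason"].to_numpy(dtype=object),
        _day_numbers(rows["post_delisting_death_date"], epoch).to_numpy(),
        np.full(len(rows), cutoff_day),
        horizon_days,
    )
    rows["time_days"] = time
    rows["event"] = event
    rows["censor_cause"] = [CAUSES[c] for c in cause]
    rows["stratum"] = rows["country"].astype(str)
    rows = rows[rows["time_days"] > 0].reset_index(drop=True)
    return rows
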