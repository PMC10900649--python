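"""Waitlist-registry domain model, CSV I/O, validation, and cohort splitting.

The registry is three tables, mirroring how transplant registries are
exported:

* ``registrations`` — one row per listing episode: patient, center, country,
  registration/exit dates, exit reason, and post-delisting death follow-up;
* ``reports`` — dated biomarker reports (creatinine, bilirubin, INR,
  dialysis flag);
* ``statuses`` — non-transplantable (NT) intervals during which a candidate
  cannot receive offers.

Dates are whole calendar days (``datetime64[ns]`` truncated to days); all
durations are integer days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Registry",
    "ExclusionReport",
    "read_registry",
    "write_registry",
    "validate_registry",
    "center_split",
    "EXIT_REASONS",
]

EXIT_REASONS = ("death", "transplant", "delisting", "censored")

_REGISTRATION_COLS = [
    "patient_id",
    "center_id",
    "country",
    "registration_date",
    "exit_date",
    "exit_reason",
    "post_delisting_death_date",
    "post_delisting_followup_days",
]
_REPORT_COLS = ["patient_id", "report_date", "creatinine", "bilirubin", "inr", "dialysis"]
_STATUS_COLS = ["patient_id", "start_date", "end_date", "status"]

_DATE_COLS = {
    "registrations": ["registration_date", "exit_date", "post_delisting_death_date"],
    "reports": ["report_date"],
    "statuses": ["start_date", "end_date"],
}


class SchemaError(ValueError):
    """A CSV file does not conform to the expected registry schema."""


@dataclass
class Registry:
    """In-memory waitlist registry: three pandas tables."""

    registrations: pd.DataFrame
    reports: pd.DataFrame
    statuses: pd.DataFrame
    cutoff_date: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if self.cutoff_date is not None:
            self.cutoff_date = pd.Timestamp(self.cutoff_date)

    @property
    def n_registrations(self) -> int:
        return len(self.registrations)

    def reports_for(self, patient_id) -> pd.DataFrame:
        return self.reports[self.reports["patient_id"] == patient_id]

    def subset_patients(self, patient_ids) -> "Registry":
        """Restrict all three tables to the given patients (order preserved)."""
        ids = set(patient_ids)
        return Registry(
            registrations=self.registrations[
                self.registrations["patient_id"].isin(ids)
            ].reset_index(drop=True),
            reports=self.reports[self.reports["patient_id"].isin(ids)].reset_index(drop=True),
            statuses=self.statuses[self.statuses["patient_id"].isin(ids)].reset_index(drop=True),
            cutoff_date=self.cutoff_date,
        )


@dataclass
class ExclusionReport:
    """Counts of registrations removed during validation, by reason."""

    counts: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_dates(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        raw = df[c]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"{path}: unparseable date in column '{c}' at row {i}: {raw.iloc[i]!r}")
        df[c] = parsed
    return df


def read_registry(registrations_path, reports_path, statuses_path, cutoff_date=None) -> Registry:
    """Read the three registry CSVs; parse dates; apply no filtering.

    Row order is preserved. A missing column raises :class:`SchemaError`
    naming the column; an unparseable date raises with the row index.
    """
    regs = pd.read_csv(registrations_path)
    _check_columns(regs, _REGISTRATION_COLS, registrations_path)
    regs = _parse_dates(regs, _DATE_COLS["registrations"], registrations_path)

    reports = pd.read_csv(reports_path)
    _check_columns(reports, _REPORT_COLS, reports_path)
    reports = _parse_dates(reports, _DATE_COLS["reports"], reports_path)
    reports["dialysis"] = reports["dialysis"].astype(int).astype(bool)

    statuses = pd.read_csv(statuses_path)
    if len(statuses) == 0 and list(statuses.columns) != _STATUS_COLS:
        statuses = pd.DataFrame(columns=_STATUS_COLS)
    _check_columns(statuses, _STATUS_COLS, statuses_path)
    statuses = _parse_dates(statuses, _DATE_COLS["statuses"], statuses_path)

    bad_reason = ~regs["exit_reason"].isna() & ~regs["exit_reason"].isin(EXIT_REASONS)
    if bad_reason.any():
        i = int(np.flatnonzero(bad_reason.to_numpy())[0])
        raise SchemaError(
            f"{registrations_path}: unknown exit_reason {regs['exit_reason'].iloc[i]!r} at row {i}"
        )
    return Registry(regs, reports, statuses, cutoff_date=cutoff_date)


def write_registry(registry: Registry, registrations_path, reports_path, statuses_path) -> None:
    """Write the three tables as ISO-dated CSVs (round-trips with read_registry)."""

    def _fmt(df, date_cols):
        out = df.copy()
        for c in date_cols:
            out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
        return out

    _fmt(registry.registrations, _DATE_COLS["registrations"]).to_csv(registrations_path, index=False)
    rep = _fmt(registry.reports, _DATE_COLS["reports"]).copy()
    rep["dialysis"] = rep["dialysis"].astype(int)
    rep.to_csv(reports_path, index=False)
    _fmt(registry.statuses, _DATE_COLS["statuses"]).to_csv(statuses_path, index=False)


def validate_registry(registry: Registry) -> tuple[Registry, ExclusionReport]:
    """Apply exclusion rules; return the cleaned registry and an exclusion report.

    Rules:

    * a registration whose registration-time report (first report on/after
      the registration date) has any biomarker <= 0 — the "impossible
      values" pattern, e.g. all zeroes — is excluded
      (reason ``impossible_biomarkers``);
    * a registration with no biomarker report on or after its registration
      date is excluded (reason ``no_listing_report``) since listing-time
      reporting is mandatory;
    * reports for patients absent from the registrations table are dropped
      (counted under ``orphan_reports``).
    """
    regs = registry.registrations
    reports = registry.reports.sort_values(["patient_id", "report_date"], kind="stable")
    report = ExclusionReport()

    first_report = {}
    for pid, grp in reports.groupby("patient_id", sort=False):
        first_report[pid] = grp

    keep = np.ones(len(regs), dtype=bool)
    n_impossible = 0
    n_noreport = 0
    for i, row in enumerate(regs.itertuples(index=False)):
        grp = first_report.get(row.patient_id)
        listing = None
        if grp is not None:
            after = grp[grp["report_date"] >= row.registration_date]
            if len(after):
                listing = after.iloc[0]
        if listing is None:
            keep[i] = False
            n_noreport += 1
            continue
        if min(listing["creatinine"], listing["bilirubin"], listing["inr"]) <= 0:
            keep[i] = False
            n_impossible += 1
    if n_impossible:
        report.counts["impossible_biomarkers"] = n_impossible
    if n_noreport:
        report.counts["no_listing_report"] = n_noreport

    kept = regs[keep].reset_index(drop=True)
    valid_ids = set(kept["patient_id"])
    orphan = ~registry.reports["patient_id"].isin(valid_ids)
    if orphan.any():
        report.counts["orphan_reports"] = int(orphan.sum())

    cleaned = Registry(
        registrations=kept,
        reports=registry.reports[~orphan].reset_index(drop=True),
        statuses=registry.statuses[
            registry.statuses["patient_id"].isin(valid_ids)
        ].reset_index(drop=True),
        cutoff_date=registry.cutoff_date,
    )
    # invariant checks on the cleaned registry
    r = cleaned.registrations
    has_exit = r["exit_date"].notna()
    if (r.loc[has_exit, "exit_date"] < r.loc[has_exit, "registration_date"]).any():
        report.notes.append("exit_date before registration_date encountered")
    return cleaned, report


def center_split(
    registry: Registry,
    dev_fraction: float,
    single_center_countries=(),
    seed: int = 0,
) -> tuple[Registry, Registry]:
    """Development/validation split for geographical validation.

    For countries not listed in ``single_center_countries``, whole listing
    centers are assigned to one cohort, greedily by decreasing center size
    (ties broken on center_id), so each country's development patient share
    tracks ``dev_fraction`` as closely as possible.  Countries listed in
    ``single_center_countries`` are split at the patient level, uniformly at
    random with probability ``dev_fraction``.
    """
    if not 0 < dev_fraction < 1:
        raise ValueError("dev_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    regs = registry.registrations
    single = set(single_center_countries)
    dev_patients: list = []
    val_patients: list = []

    for country, cgrp in regs.groupby("country", sort=True):
        patients = cgrp.drop_duplicates("patient_id")
        if country in single:
            u = rng.random(len(patients))
            dev_patients.extend(patients.loc[u < dev_fraction, "patient_id"])
            val_patients.extend(patients.loc[u >= dev_fraction, "patient_id"])
            continue
        sizes = patients.groupby("center_id")["patient_id"].count()
        if len(sizes) == 1:
            raise ValueError(
                f"country {country!r} has a single center; list it in "
                "single_center_countries to split it at the patient level"
            )
        total = int(sizes.sum())
        order = sizes.sort_index().sort_values(ascending=False, kind="stable")
        n_dev = 0
        dev_centers = set()
        for center_id, size in order.items():
            if abs((n_dev + size) / total - dev_fraction) <= abs(n_dev / total - dev_fraction):
                dev_centers.add(center_id)
                n_dev += int(size)
        in_dev = patients["center_id"].isin(dev_centers)
        dev_patients.extend(patients.loc[in_dev, "patient_id"])
        val_patients.extend(patients.loc[~in_dev, "patient_id"])

    return registry.subset_patients(dev_patients), registry.subset_patients(val_patients)
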