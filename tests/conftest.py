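import numpy as np
import pandas as pd
import pytest

from dynremeld.registry import Registry


def make_registry(
    registrations: list[dict],
    reports: list[dict],
    statuses: list[dict] | None = None,
    cutoff="2016-12-31",
) -> Registry:
    """Build a small in-memory registry from plain dicts (dates as strings)."""
    regs = pd.DataFrame(registrations)
    for c in ("exit_date", "post_delisting_death_date"):
        if c not in regs:
            regs[c] = pd.NaT
    if "post_delisting_followup_days" not in regs:
        regs["post_delisting_followup_days"] = pd.NA
    if "exit_reason" not in regs:
        regs["exit_reason"] = "censored"
    if "center_id" not in regs:
        regs["center_id"] = "C0"
    if "country" not in regs:
        regs["country"] = "XX"
    for c in ("registration_date", "exit_date", "post_delisting_death_date"):
        regs[c] = pd.to_datetime(regs[c])

    reps = pd.DataFrame(reports)
    for c, default in (("creatinine", 1.0), ("bilirubin", 1.0), ("inr", 1.0), ("dialysis", False)):
        if c not in reps:
            reps[c] = default
    reps["report_date"] = pd.to_datetime(reps["report_date"])
    reps["dialysis"] = reps["dialysis"].astype(bool)

    if statuses:
        st = pd.DataFrame(statuses)
        st["start_date"] = pd.to_datetime(st["start_date"])
        st["end_date"] = pd.to_datetime(st.get("end_date"))
        if "status" not in st:
            st["status"] = "NT"
    else:
        st = pd.DataFrame(columns=["patient_id", "start_date", "end_date", "status"])
    return Registry(regs, reps, st, cutoff_date=cutoff)


@pytest.fixture
def tiny_registry():
    """Three patients: one death, one transplant, one delisting-then-death."""
    return make_registry(
        registrations=[
            {"patient_id": "A", "registration_date": "2015-01-05", "exit_date": "2015-03-01",
             "exit_reason": "death"},
            {"patient_id": "B", "registration_date": "2015-01-10", "exit_date": "2015-02-10",
             "exit_reason": "transplant"},
            {"patient_id": "C", "registration_date": "2015-01-01", "exit_date": "2015-02-20",
             "exit_reason": "delisting", "post_delisting_death_date": "2015-03-10"},
        ],
        reports=[
            {"patient_id": "A", "report_date": "2015-01-05", "creatinine": 1.2,
             "bilirubin": 3.0, "inr": 1.5},
            {"patient_id": "A", "report_date": "2015-02-01", "creatinine": 2.0,
             "bilirubin": 6.0, "inr": 1.9},
            {"patient_id": "B", "report_date": "2015-01-10", "creatinine": 0.9,
             "bilirubin": 1.5, "inr": 1.1},
            {"patient_id": "C", "report_date": "2015-01-01", "creatinine": 1.6,
             "bilirubin": 9.0, "inr": 2.2, "dialysis": True},
        ],
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240228)
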