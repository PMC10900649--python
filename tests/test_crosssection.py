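import numpy as np
import pandas as pd
import pytest

from dynremeld.crosssection import (
    active_at,
    build_cross_section_dataset,
    build_from_registration_dataset,
    cross_section_dates,
    encode_outcome,
    last_report_before,
)
from dynremeld.simulate import SimulationConfig, simulate_registry

from conftest import make_registry


class TestCrossSectionDates:
    def test_weekly_grid_endpoints(self):
        dates = cross_section_dates("2006-12-31", "2019-12-22", 7)
        assert dates[0] == pd.Timestamp("2006-12-31")
        assert dates[-1] == pd.Timestamp("2019-12-22")

    def test_count_matches_day_arithmetic(self):
        start, end = pd.Timestamp("2006-12-31"), pd.Timestamp("2019-12-22")
        dates = cross_section_dates(start, end, 7)
        assert len(dates) == (end - start).days // 7 + 1

    def test_degenerate_and_invalid(self):
        assert list(cross_section_dates("2015-03-01", "2015-03-01", 7)) == [
            pd.Timestamp("2015-03-01")
        ]
        with pytest.raises(ValueError):
            cross_section_dates("2015-01-01", "2015-02-01", 0)


class TestActiveAt:
    reg = {"patient_id": "A", "registration_date": pd.Timestamp("2015-01-05"),
           "exit_date": pd.Timestamp("2015-03-01")}
    nt = pd.DataFrame({"patient_id": ["A"], "start_date": [pd.Timestamp("2015-01-08")],
                       "end_date": [pd.Timestamp("2015-02-01")], "status": ["NT"]})

    def test_active_between_listing_and_exit(self):
        assert active_at(self.reg, None, "2015-01-06")

    def test_nt_interval_blocks(self):
        assert not active_at(self.reg, self.nt, "2015-01-10")
        assert active_at(self.reg, self.nt, "2015-02-01")  # NT interval is half-open

    def test_exit_day_not_active(self):
        assert not active_at(self.reg, None, "2015-03-01")


class TestLastReportBefore:
    reports = pd.DataFrame(
        {
            "patient_id": "A",
            "report_date": pd.to_datetime(["2015-01-01", "2015-01-21", "2015-01-21"]),
            "creatinine": [1.0, 2.0, 3.0],
        }
    )

    def test_picks_most_recent(self):
        assert last_report_before(self.reports, "2015-01-26")["creatinine"] == 3.0
        assert last_report_before(self.reports, "2015-01-11")["creatinine"] == 1.0

    def test_same_day_tie_goes_to_later_ingested(self):
        assert last_report_before(self.reports, "2015-01-21")["creatinine"] == 3.0

    def test_absent_when_no_prior_report(self):
        assert last_report_before(self.reports, "2014-12-31") is None


class TestEncodeOutcome:
    def _reg(self, **kw):
        base = {"exit_date": pd.NaT, "exit_reason": None, "post_delisting_death_date": pd.NaT}
        base.update(kw)
        return base

    def test_delisting_death_within_90_days_is_event(self):
        reg = self._reg(exit_date=pd.Timestamp("2015-02-10"), exit_reason="delisting",
                        post_delisting_death_date=pd.Timestamp("2015-03-12"))
        t, event, cause = encode_outcome(reg, "2015-01-01")
        assert (t, event, cause) == (40.0, True, None)

    def test_delisting_late_death_censors(self):
        reg = self._reg(exit_date=pd.Timestamp("2015-02-10"), exit_reason="delisting",
                        post_delisting_death_date=pd.Timestamp("2015-06-01"))
        t, event, cause = encode_outcome(reg, "2015-01-01")
        assert (t, event, cause) == (40.0, False, "delisting")

    def test_transplant_censors_at_exit(self):
        reg = self._reg(exit_date=pd.Timestamp("2015-01-21"), exit_reason="transplant")
        assert encode_outcome(reg, "2015-01-01") == (20.0, False, "transplant")

    def test_survivor_truncated_at_horizon(self):
        reg = self._reg(exit_date=pd.Timestamp("2015-12-01"), exit_reason="death")
        assert encode_outcome(reg, "2015-01-01") == (90.0, False, "horizon")

    def test_cutoff_before_horizon(self):
        reg = self._reg()
        assert encode_outcome(reg, "2015-01-01", cutoff="2015-02-01") == (
            31.0, False, "administrative")


def brute_force_rows(registry, dates, horizon=90):
    """O(patients x dates) membership oracle re-deriving the row set."""
    out = []
    for _, reg in registry.registrations.iterrows():
        mine = registry.reports[
            registry.reports["patient_id"] == reg["patient_id"]
        ].sort_values("report_date", kind="stable")
        for d in dates:
            if not active_at(reg, registry.statuses, d, cutoff=registry.cutoff_date):
                continue
            rep = last_report_before(mine, d)
            if rep is None:
                continue
            t, event, cause = encode_outcome(reg, d, horizon, cutoff=registry.cutoff_date)
            if t <= 0:
                continue
            out.append((reg["patient_id"], pd.Timestamp(d), rep["creatinine"], t, event))
    return sorted(out)


@pytest.fixture(scope="module")
def oracle_registry():
    registry, _ = simulate_registry(
        SimulationConfig(n_patients=20, seed=77, window_start="2015-01-01",
                         window_end="2015-12-31", nt_fraction=0.3)
    )
    return registry


def test_cross_section_rows_match_day_scan_oracle(oracle_registry):
    dates = cross_section_dates("2015-01-01", "2015-12-31", 7)
    rows = build_cross_section_dataset(oracle_registry, dates)
    got = sorted(
        (r.patient_id, r.cs_date, r.creatinine, r.time_days, r.event)
        for r in rows.itertuples(index=False)
    )
    assert got == brute_force_rows(oracle_registry, dates)


def test_no_future_biomarker_leakage(oracle_registry):
    dates = cross_section_dates("2015-01-01", "2015-12-31", 7)
    rows = build_cross_section_dataset(oracle_registry, dates)
    assert (rows["report_date"] <= rows["cs_date"]).all()
    assert (rows["time_days"] <= 90).all()
    assert (rows["time_days"] > 0).all()
    assert (rows.loc[rows["event"], "censor_cause"].isna()).all()


def test_multiple_cross_sections_per_patient():
    registry = make_registry(
        [{"patient_id": "A", "registration_date": "2015-01-01",
          "exit_date": "2015-03-15", "exit_reason": "death"}],
        [{"patient_id": "A", "report_date": "2015-01-01"}],
    )
    dates = cross_section_dates("2015-01-01", "2015-12-31", 7)
    rows = build_cross_section_dataset(registry, dates)
    assert len(rows) == 11  # weekly grid dates inside [listing, exit)
    # early-exit patient may never reach a cross-section
    registry2 = make_registry(
        [{"patient_id": "B", "registration_date": "2015-01-02",
          "exit_date": "2015-01-05", "exit_reason": "transplant"}],
        [{"patient_id": "B", "report_date": "2015-01-02"}],
    )
    assert len(build_cross_section_dataset(registry2, dates)) == 0


def test_from_registration_dataset(tiny_registry):
    rows = build_from_registration_dataset(tiny_registry)
    assert len(rows) == 3
    a = rows[rows["patient_id"] == "A"].iloc[0]
    assert a["creatinine"] == 1.2  # listing report, not the later update
    assert a["stratum"] == "XX"
    c = rows[rows["patient_id"] == "C"].iloc[0]
    assert c["event"]  # delisted then died within 90 days
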