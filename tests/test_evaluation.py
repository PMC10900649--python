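import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from dynremeld.evaluation import (
    absolute_risk_table,
    bootstrap_compare,
    dedup_first_cross_section,
    km_first_reach,
    truncated_cindex,
)
from dynremeld.scores import DYNREMELD, UNOS_MELD, ScoreDefinition

from conftest import make_registry


def pairwise_oracle(time, event, score, horizon, G):
    """O(n^2) double loop re-deriving the weighted truncated concordance."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        if not (event[i] and time[i] < horizon):
            continue
        w = 1.0 / G(np.array([time[i] - 0.5]))[0] ** 2
        for j in range(n):
            if time[j] > time[i]:
                den += w
                if score[i] > score[j]:
                    num += w
                elif score[i] == score[j]:
                    num += 0.5 * w
    return num / den


class TestTruncatedCIndex:
    def test_perfect_discrimination(self):
        time = np.arange(1, 21, dtype=float)
        res = truncated_cindex(time, np.ones(20, bool), -time, censoring_correction="none")
        assert res.estimate == 1.0

    def test_uninformative_score_near_half(self, rng):
        n = 4000
        time = np.ceil(rng.exponential(40, n))
        event = time <= 90
        time = np.minimum(time, 90)
        score = rng.normal(size=n)  # independent of outcome
        res = truncated_cindex(time, event, score)
        assert abs(res.estimate - 0.5) < 0.03

    def test_matches_pairwise_oracle_exactly(self, rng):
        n = 20
        time = rng.integers(1, 95, n).astype(float)
        event = rng.random(n) < 0.6
        score = rng.normal(size=n).round(1)  # coarse -> some score ties
        km = KaplanMeierFitter().fit(time, event_observed=~event)
        G = lambda t: km.survival_function_at_times(np.atleast_1d(t)).to_numpy()
        mine = truncated_cindex(time, event, score, censoring_correction=G)
        oracle = pairwise_oracle(time, event, score, 90, G)
        assert mine.estimate == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        n = 300
        time = np.ceil(rng.exponential(40, n))
        event = time <= 90
        time = np.minimum(time, 90)
        score = rng.normal(size=n)
        a = truncated_cindex(time, event, score).estimate
        b = truncated_cindex(time, event, np.exp(3 * score)).estimate
        assert a == pytest.approx(b, abs=1e-12)

    def test_correction_inert_without_censoring(self, rng):
        n = 200
        time = rng.integers(1, 90, n).astype(float)
        event = np.ones(n, bool)  # everyone fails before the horizon
        score = rng.normal(size=n)
        plain = truncated_cindex(time, event, score, censoring_correction="none")
        km = truncated_cindex(time, event, score, censoring_correction="km")
        assert plain.estimate == pytest.approx(km.estimate, abs=1e-12)

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            truncated_cindex([10, 20], [False, False], [1, 2])


def _score_rows(rng, n=800):
    rows = pd.DataFrame(
        {
            "patient_id": rng.integers(0, n // 3, n),
            "creatinine": np.exp(rng.normal(0.1, 0.3, n)),
            "bilirubin": np.exp(rng.normal(0.9, 0.8, n)),
            "inr": np.exp(rng.normal(0.25, 0.2, n)),
            "dialysis": rng.random(n) < 0.1,
        }
    )
    risk = 0.1 * rows.bilirubin + rows.inr
    t = np.ceil(rng.exponential(60 / risk))
    rows["time_days"] = np.minimum(t, 90)
    rows["event"] = t <= 90
    return rows


class TestBootstrapCompare:
    def test_identical_scores_give_zero_delta(self, rng):
        rows = _score_rows(rng)
        delta, se, p = bootstrap_compare(rows, UNOS_MELD, UNOS_MELD, n_boot=10, seed=4)
        assert delta == 0.0 and se == 0.0 and p == 1.0

    def test_deterministic_given_seed(self, rng):
        rows = _score_rows(rng)
        r1 = bootstrap_compare(rows, UNOS_MELD, DYNREMELD, n_boot=15, seed=7)
        r2 = bootstrap_compare(rows, UNOS_MELD, DYNREMELD, n_boot=15, seed=7)
        assert r1 == r2

    def test_better_score_wins(self, rng):
        """A score aligned with the generating hazard beats a corrupted one."""
        n = 4000
        rows = _score_rows(rng, n)
        wide = {b: (1e-9, np.inf) for b in ("creatinine", "bilirubin", "inr")}
        good = ScoreDefinition("good", 0, 0.0, 1.0, 6.0, bounds=wide)
        bad = ScoreDefinition("bad", 0, 5.0, 0.1, 0.1, bounds=wide)
        delta, se, p = bootstrap_compare(rows, good, bad, n_boot=30, seed=1)
        assert delta > 0 and p < 0.05

    def test_requires_two_replicates(self, rng):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_compare(_score_rows(rng), UNOS_MELD, DYNREMELD, n_boot=1)


def test_dedup_keeps_first_active_cross_section():
    rows = pd.DataFrame(
        {
            "patient_id": ["A", "A", "A", "B"],
            "report_date": pd.to_datetime(["2015-01-01", "2015-01-01", "2015-02-01",
                                           "2015-01-01"]),
            "cs_date": pd.to_datetime(["2015-01-11", "2015-01-04", "2015-02-08",
                                       "2015-01-04"]),
            "creatinine": 1.0, "bilirubin": 2.0, "inr": 1.1, "dialysis": False,
        }
    )
    out = dedup_first_cross_section(rows)
    assert len(out) == 3
    a_first = out[(out.patient_id == "A") &
                  (out.report_date == "2015-01-01")]["cs_date"].iloc[0]
    assert a_first == pd.Timestamp("2015-01-04")


class TestAbsoluteRiskTable:
    def test_risks_increase_with_score(self, rng):
        rows = _score_rows(rng, 3000)
        tab = absolute_risk_table(rows, UNOS_MELD, score_range=range(8, 30)).table
        fitted = tab["risk"].to_numpy()
        assert (np.diff(fitted) > 0).all()
        assert ((fitted >= 0) & (fitted <= 1)).all()

    def test_null_score_gives_flat_pooled_risk(self, rng):
        """With the score shuffled, every per-score risk collapses to the
        pooled 90-day estimate."""
        rows = _score_rows(rng, 3000)
        shuffled = rows.copy()
        # break the score-outcome link by permuting biomarkers jointly
        perm = rng.permutation(len(rows))
        for c in ("creatinine", "bilirubin", "inr", "dialysis"):
            shuffled[c] = rows[c].to_numpy()[perm]
        tab = absolute_risk_table(shuffled, UNOS_MELD, score_range=range(10, 26)).table
        spread = tab["risk"].max() - tab["risk"].min()
        assert spread < 0.08
        km = KaplanMeierFitter().fit(rows["time_days"], rows["event"])
        pooled = 1 - float(km.survival_function_at_times(90).iloc[0])
        assert tab["risk"].median() == pytest.approx(pooled, abs=0.05)

    def test_bootstrap_cis_bracket_estimate(self, rng):
        rows = _score_rows(rng, 1500)
        tab = absolute_risk_table(rows, UNOS_MELD, score_range=range(10, 20),
                                  n_boot=20, seed=3).table
        assert (tab["ci_low"] <= tab["risk"] + 1e-9).all()
        assert (tab["risk"] <= tab["ci_high"] + 1e-9).all()


class TestKMFirstReach:
    def test_deterministic_deaths_give_risk_one(self):
        regs, reps = [], []
        for i in range(5):
            regs.append({"patient_id": f"P{i}", "registration_date": "2015-01-01",
                         "exit_date": "2015-01-11", "exit_reason": "death"})
            reps.append({"patient_id": f"P{i}", "report_date": "2015-01-01",
                         "creatinine": 2.0, "bilirubin": 5.0, "inr": 2.0})
        registry = make_registry(regs, reps)
        tab = km_first_reach(registry, UNOS_MELD, score_range=range(6, 41)).table
        assert len(tab) == 1  # all five share one score stratum
        assert tab["risk"].iloc[0] == pytest.approx(1.0)
        assert (tab["n"] == 5).all()

    def test_one_observation_per_patient_per_stratum(self):
        regs = [{"patient_id": "A", "registration_date": "2015-01-01",
                 "exit_date": "2015-06-01", "exit_reason": "death"}]
        reps = [
            {"patient_id": "A", "report_date": d, "creatinine": 2.0,
             "bilirubin": 5.0, "inr": 2.0}
            for d in ("2015-01-01", "2015-02-01", "2015-03-01")
        ]
        # one more patient so the stratum passes the minimum size
        regs.append({"patient_id": "B", "registration_date": "2015-01-01",
                     "exit_date": "2015-07-01", "exit_reason": "death"})
        reps.append({"patient_id": "B", "report_date": "2015-01-01",
                     "creatinine": 2.0, "bilirubin": 5.0, "inr": 2.0})
        registry = make_registry(regs, reps)
        tab = km_first_reach(registry, UNOS_MELD, score_range=range(6, 41),
                             min_patients=2).table
        assert (tab["n"] == 2).all()  # repeat reports at the same score ignored
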