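from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from asthmaflow.analytics import (
    attrition_curve,
    good_day_monthly,
    hour_histogram,
    likert_summary,
    pppw_rate,
    rank_sum_compare,
    sus_score,
    trigger_frequency,
    weekly_active_fraction,
    weeks_with_login,
    zone_distribution,
)
from asthmaflow.event_log import EventLog, EventRecord, EventType
from asthmaflow.journal import JournalEntry
from asthmaflow.simulator import SimParams, simulate_cohort

from conftest import ts


def login(patient, days, hours=16):
    return EventRecord(patient, ts(days, hours), EventType.LOGIN)


def zone_calc(patient, days, zone):
    return EventRecord(
        patient, ts(days), EventType.ZONE_CALC, {"zone": zone, "basis": "symptoms_only"}
    )


class TestPppwRate:
    def test_denominator_identity(self):
        assert pppw_rate(6396, 123, 52) == pytest.approx(1.0)

    def test_zero_events(self):
        assert pppw_rate(0, 123, 52) == 0.0

    def test_linearity(self):
        assert pppw_rate(2 * 777, 10, 5) == pytest.approx(2 * pppw_rate(777, 10, 5))

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            pppw_rate(10, 0, 52)


class TestActivity:
    def test_weekly_active_fraction_counts_distinct_patients(self):
        # 3 patients enrolled at T0; two active in week 2 (days 7-13)
        enr = {f"P{i}": ts(0) for i in range(3)}
        log = EventLog((login("P0", 8), login("P0", 9), login("P1", 10), login("P2", 20)))
        assert weekly_active_fraction(log, 3, 2, enr) == pytest.approx(2 / 3)
        assert weekly_active_fraction(log, 3, 1, enr) == 0.0

    def test_empty_log(self):
        assert weekly_active_fraction(EventLog(), 5, 1, {}) == 0.0

    def test_attrition_curve_composition(self):
        enr = {"P0": ts(0)}
        log = EventLog(tuple(login("P0", 7 * w + 1) for w in range(52)))
        curve = attrition_curve(log, 1, enr)
        assert curve.shape == (52,)
        assert np.all(curve == 1.0)
        assert curve[3] == weekly_active_fraction(log, 1, 4, enr)

    def test_single_patient_week_one(self):
        enr = {"P0": ts(0), "P1": ts(0)}
        curve = attrition_curve(EventLog((login("P0", 2),)), 2, enr)
        assert curve[0] == 0.5
        assert np.all(curve[1:] == 0.0)

    def test_weeks_with_login_distinct_weeks(self):
        enr = ts(0)
        log = EventLog((login("P0", 1), login("P0", 2), login("P0", 9)))
        assert weeks_with_login(log, "P0", enr) == 2
        assert weeks_with_login(log, "P9", enr) == 0

    def test_hour_histogram_bins_local_hour(self):
        # 19:05 Toronto (EDT, UTC-4) in June is 23:05 UTC
        from datetime import datetime, timezone

        instant = datetime(2013, 6, 10, 23, 5, tzinfo=timezone.utc)
        log = EventLog((EventRecord("P0", instant, EventType.LOGIN),))
        hist = hour_histogram(log)
        assert hist[19] == 1 and hist.sum() == 1

    def test_hour_histogram_conserves_total(self):
        log = EventLog(tuple(login(f"P{i}", i % 20, hours=i % 24) for i in range(200)))
        assert hour_histogram(log).sum() == 200


class TestZoneAndJournalMetrics:
    def test_zone_distribution_fractions(self):
        log = EventLog(
            tuple(zone_calc("P0", 1, "green") for _ in range(3))
            + (zone_calc("P0", 2, "red"),)
        )
        dist = zone_distribution(log)
        assert dist["green"] == (3, 0.75)
        assert sum(f for _, f in dist.values()) == pytest.approx(1.0)

    def test_zone_distribution_requires_calcs(self):
        with pytest.raises(ValueError):
            zone_distribution(EventLog())

    def test_trigger_frequency_sorted_desc(self):
        entries = [
            JournalEntry("P0", ts(d), triggers=("dust",) if d < 3 else ("smoke",))
            for d in range(4)
        ]
        freq = trigger_frequency(entries)
        assert list(freq.items()) == [("dust", 3), ("smoke", 1)]
        assert sum(freq.values()) == 4

    def test_trigger_frequency_empty(self):
        assert trigger_frequency([]) == {}

    def test_good_day_monthly_two_to_one(self):
        entries = [
            JournalEntry("P0", ts(d, 12), daytime_symptoms=(d % 3 == 0))
            for d in range(30)
        ]
        table = good_day_monthly(entries, enrollments={"P0": ts(0)})
        row = table.loc[1]
        assert row["good"] == 20 and row["episode"] == 10
        assert row["pct_good"] == pytest.approx(100 * 2 / 3)

    def test_good_day_monthly_omits_empty_months(self):
        entries = [JournalEntry("P0", ts(70, 12))]  # month 3 only
        table = good_day_monthly(entries, enrollments={"P0": ts(0)})
        assert list(table.index) == [3]

    def test_good_day_any_symptomatic_entry_spoils_the_day(self):
        # both entries fall on the same Toronto calendar day
        entries = [
            JournalEntry("P0", ts(1, 0)),
            JournalEntry("P0", ts(1, 6), reliever_doses=1),
        ]
        table = good_day_monthly(entries, enrollments={"P0": ts(0)})
        assert table.loc[1, "episode"] == 1 and table.loc[1, "good"] == 0


def enumeration_rank_sum_p(a, b):
    """Independent oracle: exact two-sided p by enumerating all rank splits."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = len(a)
    observed = ranks[:n].sum()
    sums = np.array(
        [ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), n)]
    )
    p_low = np.mean(sums <= observed)
    p_high = np.mean(sums >= observed)
    return min(1.0, 2 * min(p_low, p_high))


class TestRankSum:
    def test_identical_groups_p_near_one(self):
        _, p = rank_sum_compare([1, 2, 3], [1.5, 2.5, 3.5])
        assert p > 0.5

    def test_separated_groups_exact_p(self):
        w, p = rank_sum_compare([1, 2, 3], [4, 5, 6])
        assert w == 6.0  # ranks 1+2+3
        assert p == pytest.approx(0.10)

    def test_exact_mode_matches_enumeration(self):
        rng = np.random.default_rng(11)
        for n in (2, 3, 4, 5):
            for _ in range(8):
                a = rng.normal(size=n)
                b = rng.normal(loc=rng.uniform(-2, 2), size=n)
                _, p = rank_sum_compare(a, b)
                assert p == pytest.approx(enumeration_rank_sum_p(a, b), abs=1e-12)

    def test_shift_monotonicity(self):
        a = [3.0, 5.0, 7.0, 9.0]
        p_prev = None
        for shift in (0.0, 2.0, 4.0, 8.0):
            _, p = rank_sum_compare(a, [x + shift for x in a])
            if p_prev is not None:
                assert p <= p_prev + 1e-12
            p_prev = p

    def test_ties_use_corrected_approximation(self):
        a = [1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6]
        b = [2, 2, 3, 3, 4, 4, 5, 5, 6, 6, 7]
        _, p = rank_sum_compare(a, b)
        assert 0 < p < 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_compare([], [1, 2])


class TestQuestionnaires:
    @pytest.mark.parametrize(
        "responses, expected",
        [
            ([5, 1] * 5, 100.0),
            ([3] * 10, 50.0),
            ([1, 5] * 5, 0.0),
        ],
    )
    def test_sus_extremes_and_midpoint(self, responses, expected):
        assert sus_score(responses) == expected

    def test_sus_input_validation(self):
        with pytest.raises(ValueError):
            sus_score([3] * 9)
        with pytest.raises(ValueError):
            sus_score([0] + [3] * 9)

    def test_likert_agreement_share(self):
        rows = (
            [("R%d" % i, "helpful", 4 + i % 2) for i in range(74)]
            + [("D%d" % i, "helpful", 1 + i % 2) for i in range(21)]
            + [("N%d" % i, "helpful", 3) for i in range(21)]
        )
        table = pd.DataFrame(rows, columns=["respondent_id", "item_id", "response"])
        summary = likert_summary(table, "helpful")
        assert summary["n"] == 116
        assert summary["pct_agree"] == 63.8
        assert summary["pct_disagree"] == 18.1

    def test_likert_all_neutral(self):
        table = pd.DataFrame(
            [("R1", "q", 3), ("R2", "q", 3)],
            columns=["respondent_id", "item_id", "response"],
        )
        s = likert_summary(table, "q")
        assert (s["pct_agree"], s["pct_disagree"], s["pct_neutral"]) == (0.0, 0.0, 100.0)

    def test_likert_buckets_sum_to_100(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            [(f"R{i}", "q", int(rng.integers(1, 6))) for i in range(57)],
            columns=["respondent_id", "item_id", "response"],
        )
        s = likert_summary(table, "q")
        assert s["pct_agree"] + s["pct_disagree"] + s["pct_neutral"] == pytest.approx(
            100.0, abs=0.2
        )

    def test_likert_missing_item_rejected(self):
        table = pd.DataFrame(columns=["respondent_id", "item_id", "response"])
        with pytest.raises(ValueError):
            likert_summary(table, "nope")


def test_metrics_match_pandas_recount_on_simulated_log():
    """Every rate/fraction agrees with an independent DataFrame recount."""
    profiles, log = simulate_cohort(SimParams(n_patients=12, n_weeks=10, seed=5))
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in log],
            "timestamp": [r.timestamp for r in log],
            "event_type": [r.event_type.value for r in log],
            "zone": [r.payload.get("zone") for r in log],
        }
    )
    enr = {p.patient_id: p.enrollment for p in profiles}

    logins = frame[frame.event_type == "login"]
    assert pppw_rate(len(logins), 12, 10) == pytest.approx(len(logins) / 120)

    # weekly active, week 2 (enrollment-relative local calendar days)
    from zoneinfo import ZoneInfo

    tzinfo = ZoneInfo("America/Toronto")
    week = (
        logins.assign(
            w=[
                (
                    ts_.astimezone(tzinfo).date()
                    - enr[pid].astimezone(tzinfo).date()
                ).days
                // 7
                + 1
                for pid, ts_ in zip(logins.patient_id, logins.timestamp)
            ]
        )
        .query("w == 2")
        .patient_id.nunique()
    )
    assert weekly_active_fraction(log, 12, 2, enr) == pytest.approx(week / 12)

    zc = frame[frame.event_type == "zone_calc"]
    dist = zone_distribution(log)
    for zone, share in (zc.zone.value_counts(normalize=True)).items():
        assert dist[zone][1] == pytest.approx(share)
    assert sum(f for _, f in dist.values()) == pytest.approx(1.0)

    assert hour_histogram(log).sum() == len(logins)
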