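from datetime import timedelta

import pytest
from hypothesis import given, strategies as st

from asthmaflow.journal import JournalEntry, WindowAggregate, aggregate_window
from asthmaflow.profiles import Zone, ZoneThresholds
from asthmaflow.zone_engine import (
    Basis,
    SymptomCriteria,
    apply_reset,
    assess_zone,
    classify_pef,
    classify_symptoms,
)

from conftest import ts

TH = ZoneThresholds(green_lower=450, yellow_lower=300)


def entry(days=0, hours=12, **kwargs):
    return JournalEntry(patient_id="P0001", timestamp=ts(days, hours), **kwargs)


class TestClassifyPef:
    @pytest.mark.parametrize(
        "pef, expected",
        [
            (450, Zone.GREEN),  # green lower bound inclusive
            (451, Zone.GREEN),
            (449, Zone.YELLOW),
            (300, Zone.YELLOW),  # yellow lower bound inclusive
            (299, Zone.RED),
            (150, Zone.RED),
        ],
    )
    def test_banding(self, pef, expected):
        assert classify_pef(pef, TH) == expected

    def test_invalid_measurement(self):
        with pytest.raises(ValueError, match="invalid peak-flow"):
            classify_pef(0, TH)

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            classify_pef(400, ZoneThresholds(300, 450))


class TestClassifySymptoms:
    def test_all_zero_aggregate_is_green(self):
        agg = WindowAggregate(n_entries=5)
        assert classify_symptoms(agg) == Zone.GREEN

    def test_symptom_days_over_threshold_is_yellow(self):
        agg = WindowAggregate(n_entries=7, symptom_days=4)
        assert classify_symptoms(agg) == Zone.YELLOW

    def test_severe_dominates(self):
        agg = WindowAggregate(n_entries=1, severe_any=True)
        assert classify_symptoms(agg) == Zone.RED

    def test_empty_aggregate_rejected(self):
        with pytest.raises(ValueError):
            classify_symptoms(WindowAggregate())

    def test_criteria_are_configurable(self):
        agg = WindowAggregate(n_entries=7, symptom_days=5)
        relaxed = SymptomCriteria(max_symptom_days_per_week=5)
        assert classify_symptoms(agg, relaxed) == Zone.GREEN


class TestAssessZone:
    def test_no_information_is_insufficient(self, profile_factory):
        p = profile_factory()
        result = assess_zone(p, p.action_plan, [], as_of=ts(7))
        assert result.zone == Zone.INSUFFICIENT
        assert result.basis == Basis.NONE
        assert result.instruction is None

    def test_worst_of_symptoms_and_pef(self, profile_factory):
        p = profile_factory(personal_best=500)
        # symptom-quiet week but PEF in the yellow band (300 <= 400 < 450)
        entries = [entry(days=d) for d in range(5)] + [entry(days=6, pef=400.0)]
        result = assess_zone(p, p.action_plan, entries, as_of=ts(7))
        assert result.zone == Zone.YELLOW
        assert result.basis == Basis.BOTH

    def test_symptoms_only(self, profile_factory):
        p = profile_factory()
        result = assess_zone(p, p.action_plan, [entry(days=6)], as_of=ts(7))
        assert result.zone == Zone.GREEN
        assert result.basis == Basis.SYMPTOMS_ONLY
        assert result.instruction is p.action_plan.instruction_for(Zone.GREEN)

    def test_pef_only_from_standalone_reading(self, profile_factory):
        p = profile_factory(personal_best=500)
        result = assess_zone(
            p, p.action_plan, [], as_of=ts(7), pef_readings=[(ts(6), 200.0)]
        )
        assert result.zone == Zone.RED
        assert result.basis == Basis.PEF_ONLY

    def test_red_pef_dominates_green_symptoms(self, profile_factory):
        p = profile_factory(personal_best=500)
        result = assess_zone(p, p.action_plan, [entry(days=6, pef=200.0)], as_of=ts(7))
        assert result.zone == Zone.RED
        assert result.basis == Basis.BOTH

    def test_stale_pef_does_not_contribute(self, profile_factory):
        p = profile_factory(personal_best=500)
        result = assess_zone(
            p, p.action_plan, [], as_of=ts(9), pef_readings=[(ts(1), 200.0)]
        )
        assert result.zone == Zone.INSUFFICIENT

    def test_requires_pef_unresolvable_is_insufficient(self, profile_factory):
        p = profile_factory(personal_best=None, requires_pef=True)
        result = assess_zone(p, p.action_plan, [entry(days=6)], as_of=ts(7))
        assert result.zone == Zone.INSUFFICIENT
        assert result.basis == Basis.NONE

    def test_no_pef_requirement_tolerates_missing_thresholds(self, profile_factory):
        p = profile_factory(personal_best=None, requires_pef=False)
        result = assess_zone(p, p.action_plan, [entry(days=6)], as_of=ts(7))
        assert result.zone == Zone.GREEN

    def test_deterministic(self, profile_factory):
        p = profile_factory()
        entries = [entry(days=d, daytime_symptoms=True) for d in range(5)]
        r1 = assess_zone(p, p.action_plan, entries, as_of=ts(7))
        r2 = assess_zone(p, p.action_plan, entries, as_of=ts(7))
        assert r1 == r2

    @given(
        sym=st.integers(0, 7),
        wake=st.integers(0, 7),
        doses=st.integers(0, 10),
        severe=st.booleans(),
        pef_step=st.integers(6, 22),
        dim=st.sampled_from(["sym", "wake", "doses", "severe", "pef"]),
    )
    def test_worsening_never_moves_toward_green(
        self, profile_factory, sym, wake, doses, severe, pef_step, dim
    ):
        """Monotonicity: worsening any one input cannot improve the zone."""
        severity = {
            Zone.GREEN: 0,
            Zone.YELLOW: 1,
            Zone.RED: 2,
        }
        p = profile_factory(personal_best=500)

        def build(sym, wake, doses, severe, pef_step):
            entries = []
            for d in range(7):
                entries.append(
                    entry(
                        days=d,
                        daytime_symptoms=d < sym,
                        night_waking=d < wake,
                        reliever_doses=doses if d == 0 else 0,
                        severe_flag=severe and d == 0,
                    )
                )
            entries.append(entry(days=6, hours=18, pef=float(25 * pef_step)))
            return assess_zone(p, p.action_plan, entries, as_of=ts(7))

        base = build(sym, wake, doses, severe, pef_step)
        worsened = {
            "sym": (min(sym + 1, 7), wake, doses, severe, pef_step),
            "wake": (sym, min(wake + 1, 7), doses, severe, pef_step),
            "doses": (sym, wake, doses + 1, severe, pef_step),
            "severe": (sym, wake, doses, True, pef_step),
            "pef": (sym, wake, doses, severe, max(pef_step - 1, 6)),
        }[dim]
        worse = build(*worsened)
        assert severity[worse.zone] >= severity[base.zone]


class TestApplyReset:
    def test_reset_between_entries_keeps_later(self):
        early, late = entry(days=1), entry(days=3)
        kept = apply_reset([early, late], [ts(2)], as_of=ts(7))
        assert kept == [late]

    def test_reset_after_all_entries_empties(self, profile_factory):
        entries = [entry(days=d) for d in range(3)]
        kept = apply_reset(entries, [ts(5)], as_of=ts(7))
        assert kept == []
        p = profile_factory()
        assert (
            assess_zone(p, p.action_plan, kept, as_of=ts(7)).zone
            == Zone.INSUFFICIENT
        )

    def test_no_resets_is_identity(self):
        entries = [entry(days=d) for d in range(3)]
        assert apply_reset(entries, [], as_of=ts(7)) == entries

    def test_future_resets_ignored(self):
        entries = [entry(days=1)]
        assert apply_reset(entries, [ts(9)], as_of=ts(7)) == entries

    def test_entry_at_reset_instant_consumed(self):
        e = entry(days=2, hours=0)
        assert apply_reset([e], [ts(2, 0)], as_of=ts(7)) == []

    def test_assessment_ignores_information_before_reset(self, profile_factory):
        """assess(apply_reset(E, {t})) depends only on entries after t."""
        p = profile_factory()
        bad_history = [
            entry(days=d, daytime_symptoms=True, severe_flag=True) for d in range(3)
        ]
        good_recent = [entry(days=5), entry(days=6)]
        via_reset = assess_zone(
            p,
            p.action_plan,
            apply_reset(bad_history + good_recent, [ts(4)], as_of=ts(7)),
            as_of=ts(7),
        )
        only_recent = assess_zone(p, p.action_plan, good_recent, as_of=ts(7))
        assert via_reset == only_recent
        assert via_reset.zone == Zone.GREEN
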