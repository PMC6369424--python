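"""Synthetic-cohort behavior simulator.

Generates a full cohort — provider profiles, daily journals, logins, and the
derived platform events — with the behavioral structure typical of a
year-long asthma self-management deployment:

* engagement decay: the probability of being active in week *w* follows
  ``p_w = p_inf + (p0 - p_inf) * exp(-decay * w)`` (w = 0 at enrollment);
* an evening spike of logins shortly after the 19:00 reminder email;
* a morning usage block (05:00-10:00) for a share of spontaneous logins;
* surveillance bumps: activity multiplied in the two enrollment-relative
  weeks ending at each scheduled clinic-visit week (defaults 26 and 52);
* an age-50 engagement split (older patients more engaged);
* a two-state (controlled/uncontrolled) daily Markov symptom process
  consistent with mostly-controlled asthma (roughly 2 good days per
  episode day), plus peak-flow readings around a per-patient personal best.

Zone calculations are produced by running the real decision engine on the
simulated journals, and emails by running the real reminder planner on the
simulated log, so the whole pipeline is exercised end to end.  Everything is
reproducible bit-for-bit from one integer seed; each patient consumes an
independent, deterministically derived random substream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, time, timedelta, timezone
from typing import Optional, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .event_log import (
    EventLog,
    EventRecord,
    EventType,
    extend_log,
    journal_event,
)
from .journal import JournalEntry
from .profiles import (
    ActionPlan,
    AgeGroup,
    DEFAULT_TZ,
    MedClass,
    Medication,
    PatientProfile,
    Zone,
)
from .reminders import default_message_pool, emails_to_events, plan_reminders
from .zone_engine import SymptomCriteria, assess_zone

__all__ = [
    "StateParams",
    "SimParams",
    "simulate_cohort",
    "simulate_questionnaire",
    "fit_attrition_decay",
]

TRIGGER_POOL = ("dust", "pollen", "smoke", "exercise", "cold air", "pets", "stress")


@dataclass(frozen=True)
class StateParams:
    """Per-day symptom probabilities for one Markov state."""

    p_daytime: float
    p_night: float
    p_activity: float
    p_severe: float
    reliever_lam: float
    pef_mult: float  # mean PEF as a fraction of personal best


@dataclass(frozen=True)
class SimParams:
    """Simulation conditions.  The defaults are the study-like preset:

    123 patients over 52 weeks, weekly-active decay from ~0.75 to ~0.57,
    a small daily probability of responding to the 19:00 reminder, a morning
    usage block, clinic visits at weeks 26 and 52, and a symptom process
    giving roughly two good days per episode day.
    """

    n_patients: int = 123
    n_weeks: int = 52
    # Engagement decay (weekly-active probability model)
    p0: float = 0.72
    p_inf: float = 0.46
    decay: float = 0.15
    # Multiple accesses on an active day: n_logins = 1 + Poisson(lam)
    extra_logins_lam: float = 3.0
    # Probability of a login within 2 h of the 19:00 reminder, per day
    reminder_response: float = 0.03
    # Share of spontaneous logins drawn from the 05:00-10:00 morning block
    morning_weight: float = 0.35
    visit_weeks: tuple[int, ...] = (26, 52)
    visit_boost: float = 1.5
    fifty_plus_share: float = 49 / 122
    fifty_plus_boost: float = 1.5
    # Two-state daily symptom Markov chain
    stay_controlled: float = 0.95
    stay_uncontrolled: float = 0.85
    controlled: StateParams = StateParams(0.08, 0.02, 0.03, 0.001, 0.05, 0.95)
    uncontrolled: StateParams = StateParams(0.55, 0.25, 0.30, 0.02, 0.90, 0.70)
    pef_noise_sd: float = 0.06
    # Reporting probabilities, per login event
    p_journal_given_login: float = 0.83
    p_med_given_login: float = 0.10
    p_pef_given_login: float = 0.30
    # Action-plan reset behavior after a red assessment
    reset_prob: float = 0.7
    tz: str = DEFAULT_TZ
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.p0,
            self.p_inf,
            self.reminder_response,
            self.morning_weight,
            self.fifty_plus_share,
            self.stay_controlled,
            self.stay_uncontrolled,
            self.p_journal_given_login,
            self.p_med_given_login,
            self.p_pef_given_login,
            self.reset_prob,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")
        if self.p0 < self.p_inf:
            raise ValueError("p0 must be >= p_inf")
        if self.n_patients < 0 or self.n_weeks < 1:
            raise ValueError("n_patients must be >= 0 and n_weeks >= 1")

    @classmethod
    def paper_like(cls, seed: int = 0) -> "SimParams":
        """The default study-like conditions (alias for the defaults)."""
        return cls(seed=seed)


def _draw_day_flags(rng: np.random.Generator, sp: StateParams) -> dict:
    daytime = rng.random() < sp.p_daytime
    return {
        "daytime_symptoms": daytime,
        "night_waking": rng.random() < sp.p_night,
        "activity_limitation": rng.random() < sp.p_activity,
        "severe_flag": rng.random() < sp.p_severe,
        "reliever_doses": int(rng.poisson(sp.reliever_lam)),
        "triggers": tuple(
            sorted(
                rng.choice(
                    TRIGGER_POOL, size=int(rng.integers(1, 3)), replace=False
                ).tolist()
            )
        )
        if daytime
        else (),
    }


def _simulate_patient(
    params: SimParams, index: int
) -> tuple[PatientProfile, list[EventRecord]]:
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, index]))
    tzinfo = ZoneInfo(params.tz)
    utc = timezone.utc

    pid = f"P{index + 1:04d}"
    fifty_plus = rng.random() < params.fifty_plus_share
    age_mult = params.fifty_plus_boost if fifty_plus else 1.0
    # Normalize so the cohort-average engagement is unchanged by the split.
    age_mult /= (
        (1 - params.fifty_plus_share)
        + params.fifty_plus_share * params.fifty_plus_boost
    )
    personal_best = float(np.clip(rng.normal(450, 60), 250, 700))
    enroll_local = datetime(2013, 1, 7, 10, 0, tzinfo=tzinfo) + timedelta(
        days=int(rng.integers(0, 121))
    )
    enrollment = enroll_local.astimezone(utc)
    profile = PatientProfile(
        patient_id=pid,
        enrollment=enrollment,
        personal_best_pef=round(personal_best),
        medications=(
            Medication("inhaled corticosteroid", MedClass.CONTROLLER, "2 puffs BID"),
            Medication("salbutamol", MedClass.RELIEVER, "2 puffs PRN"),
        ),
        action_plan=ActionPlan.from_texts(),
        email_enabled=True,
        tz=params.tz,
        age_group=AgeGroup.FIFTY_PLUS if fifty_plus else AgeGroup.UNDER_50,
        college_educated=bool(rng.random() < 88 / 122),
        has_smartphone=bool(rng.random() < 92 / 138),
        baseline_act=int(np.clip(round(rng.normal(18.3, 4.9)), 5, 25)),
    )

    n_days = params.n_weeks * 7
    boost_weeks0 = {
        v - k for v in params.visit_weeks for k in (1, 2) if v - k >= 0
    }  # 0-based week indices in the two weeks ending at each visit
    login_u = rng.random(n_days)
    resp_u = rng.random(n_days)

    sp_by_state = {0: params.controlled, 1: params.uncontrolled}
    # Start from the chain's stationary distribution.
    q_c, q_u = 1 - params.stay_controlled, 1 - params.stay_uncontrolled
    p_start_controlled = q_u / (q_c + q_u) if (q_c + q_u) > 0 else 1.0
    state = 0 if rng.random() < p_start_controlled else 1

    events: list[EventRecord] = []
    entries: list[JournalEntry] = []  # since last reset, time-ordered
    pef_reports: list[tuple[datetime, float]] = []  # standalone readings
    win_start = 0
    pef_start = 0
    pending_reset: Optional[datetime] = None
    criteria = SymptomCriteria()

    enroll_day = enroll_local.date()
    for d in range(n_days):
        w0 = d // 7
        p_w = params.p_inf + (params.p0 - params.p_inf) * math.exp(-params.decay * w0)
        mult = age_mult * (params.visit_boost if w0 in boost_weeks0 else 1.0)
        p_w_eff = min(p_w * mult, 0.999)
        p_day = 1 - (1 - p_w_eff) ** (1 / 7)
        day = enroll_day + timedelta(days=d)

        login_times: list[datetime] = []
        if login_u[d] < p_day:
            n_logins = 1 + int(rng.poisson(params.extra_logins_lam))
            for _ in range(n_logins):
                if rng.random() < params.morning_weight:
                    hour = 5 + rng.random() * 5
                else:
                    hour = rng.random() * 24
                t_local = datetime.combine(day, time(0, 0), tzinfo) + timedelta(
                    hours=hour
                )
                login_times.append(t_local.astimezone(utc))
        if (
            profile.has_controller()
            and profile.email_enabled
            and resp_u[d] < params.reminder_response
        ):
            t_local = datetime.combine(day, time(19, 0), tzinfo) + timedelta(
                minutes=float(rng.random() * 120)
            )
            login_times.append(t_local.astimezone(utc))
        login_times.sort()

        sp = sp_by_state[state]
        day_flags: Optional[dict] = None
        for t in login_times:
            events.append(EventRecord(pid, t, EventType.LOGIN))
            report_mult = params.visit_boost if w0 in boost_weeks0 else 1.0
            if rng.random() < min(params.p_med_given_login * report_mult, 1.0):
                med = "controller" if rng.random() < 0.6 else "reliever"
                events.append(
                    EventRecord(
                        pid, t, EventType.MEDICATION_REPORT, {"med_class": med}
                    )
                )
            pef_value: Optional[float] = None
            if rng.random() < min(params.p_pef_given_login * report_mult, 1.0):
                pef_value = round(
                    personal_best
                    * sp.pef_mult
                    * (1 + rng.normal(0, params.pef_noise_sd)),
                    1,
                )
                pef_value = max(pef_value, 50.0)
                events.append(
                    EventRecord(
                        pid, t, EventType.PEAKFLOW_REPORT, {"pef": pef_value}
                    )
                )
                pef_reports.append((t, pef_value))
            if rng.random() < params.p_journal_given_login:
                if day_flags is None:
                    day_flags = _draw_day_flags(rng, sp)
                entry = JournalEntry(
                    patient_id=pid, timestamp=t, pef=pef_value, **day_flags
                )
                # Apply any action-plan reset that has come into effect.
                if pending_reset is not None and pending_reset <= t:
                    events.append(EventRecord(pid, pending_reset, EventType.RESET))
                    entries = [e for e in entries if e.timestamp > pending_reset]
                    pef_reports = [r for r in pef_reports if r[0] > pending_reset]
                    win_start = 0
                    pef_start = 0
                    pending_reset = None
                entries.append(entry)
                events.append(journal_event(entry))
                cutoff = t - timedelta(days=7)
                while win_start < len(entries) and entries[win_start].timestamp <= cutoff:
                    win_start += 1
                while pef_start < len(pef_reports) and pef_reports[pef_start][0] <= cutoff:
                    pef_start += 1
                result = assess_zone(
                    profile,
                    profile.action_plan,
                    entries[win_start:],
                    as_of=t,
                    criteria=criteria,
                    pef_readings=pef_reports[pef_start:],
                )
                events.append(
                    EventRecord(
                        pid,
                        t,
                        EventType.ZONE_CALC,
                        {"zone": result.zone.value, "basis": result.basis.value},
                    )
                )
                if (
                    result.zone == Zone.RED
                    and pending_reset is None
                    and rng.random() < params.reset_prob
                ):
                    reset_local = datetime.combine(
                        day + timedelta(days=1), time(12, 0), tzinfo
                    )
                    pending_reset = reset_local.astimezone(utc)

        # Daily state transition
        stay = params.stay_controlled if state == 0 else params.stay_uncontrolled
        if rng.random() >= stay:
            state = 1 - state

    for v in params.visit_weeks:
        if 1 <= v <= params.n_weeks:
            visit_local = datetime.combine(
                enroll_day + timedelta(days=v * 7 - 1), time(14, 0), tzinfo
            )
            events.append(
                EventRecord(pid, visit_local.astimezone(utc), EventType.CLINIC_VISIT)
            )

    return profile, events


def simulate_cohort(params: SimParams) -> tuple[list[PatientProfile], EventLog]:
    """Simulate a full cohort and its event log (reproducible from the seed).

    Journal, medication, and peak-flow events occur only on login days;
    zone calculations come from the real decision engine and emails from the
    real reminder planner run on the simulated activity.
    """
    params.validate()
    if params.n_patients == 0:
        return [], EventLog((), cohort_id="sim")

    profiles: list[PatientProfile] = []
    all_events: list[EventRecord] = []
    pool = default_message_pool(rng_seed=params.seed)
    horizon_days = timedelta(days=params.n_weeks * 7)
    for i in range(params.n_patients):
        profile, events = _simulate_patient(params, i)
        profiles.append(profile)
        patient_log = EventLog(
            tuple(e for e in events if e.event_type == EventType.LOGIN)
        )
        emails = plan_reminders(
            profile,
            patient_log,
            horizon=(profile.enrollment, profile.enrollment + horizon_days),
            pool=pool,
        )
        events.extend(emails_to_events(emails))
        all_events.extend(events)

    all_events.sort(key=lambda r: (r.timestamp, r.patient_id, r.event_type.value))
    # Day-0 activity may precede the enrollment clock time, so the window
    # opens at the start of the earliest enrollment day.
    start = min(p.enrollment for p in profiles) - timedelta(days=1)
    end = max(p.enrollment for p in profiles) + horizon_days + timedelta(days=1)
    return profiles, EventLog(tuple(all_events), cohort_id="sim", window=(start, end))


# ---------------------------------------------------------------------------
# Questionnaires
# ---------------------------------------------------------------------------

_LIKERT_ITEMS = {
    # item_id: (P(agree), P(disagree)) — remainder is neutral
    "helpful": (0.64, 0.18),
    "continue_use": (0.50, 0.26),
    "confident_zone": (0.65, 0.14),
}


def simulate_questionnaire(
    profiles: Sequence[PatientProfile], seed: int = 0
) -> pd.DataFrame:
    """Synthesize 12-month questionnaire responses (SUS items + Likert items).

    Each respondent gets a latent usability score (mean 71, SD 20 on the
    0-100 scale) mapped onto the 10 SUS items with item-level noise, plus
    three satisfaction Likert items.  Columns: respondent_id, item_id,
    response.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in profiles:
        latent = float(np.clip(rng.normal(71, 20), 2, 98)) / 100
        for i in range(1, 11):
            noisy = np.clip(latent + rng.normal(0, 0.12), 0, 1)
            level = int(np.clip(round(1 + 4 * noisy), 1, 5))
            response = level if i % 2 == 1 else 6 - level
            rows.append((p.patient_id, f"sus_{i}", response))
        for item, (p_agree, p_dis) in _LIKERT_ITEMS.items():
            u = rng.random()
            if u < p_agree:
                response = int(rng.integers(4, 6))
            elif u < p_agree + p_dis:
                response = int(rng.integers(1, 3))
            else:
                response = 3
            rows.append((p.patient_id, item, response))
    return pd.DataFrame(rows, columns=["respondent_id", "item_id", "response"])


# ---------------------------------------------------------------------------
# Attrition-decay fitting
# ---------------------------------------------------------------------------

def _decay_model(w: np.ndarray, p0: float, p_inf: float, lam: float) -> np.ndarray:
    return p_inf + (p0 - p_inf) * np.exp(-lam * w)


def fit_attrition_decay(curve: Sequence[float]) -> tuple[float, float, float]:
    """Least-squares fit of the three-parameter exponential decay model to a
    weekly-active curve (week 1 = index 0).  Returns (p0_hat, p_inf_hat,
    lambda_hat); a constant curve yields lambda 0 with both levels at the
    mean.  Deterministic given the curve.
    """
    y = np.asarray(curve, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("curve must be a 1-d sequence of at least 3 weekly values")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("curve values must lie in [0, 1]")
    if np.ptp(y) < 1e-12:
        m = float(y.mean())
        return m, m, 0.0
    w = np.arange(y.size, dtype=float)
    popt, _ = curve_fit(
        _decay_model,
        w,
        y,
        p0=[y[0], y[-1], 0.1],
        bounds=([0, 0, 0], [1, 1, 10]),
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])
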