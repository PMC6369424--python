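from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import HealthCheck, settings

from asthmaflow.profiles import (
    ActionPlan,
    MedClass,
    Medication,
    PatientProfile,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[
        HealthCheck.too_slow,
        # profile_factory is a stateless record factory, safe across examples
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")

T0 = datetime(2013, 3, 4, 15, 0, tzinfo=timezone.utc)


def ts(days: float = 0, hours: float = 0) -> datetime:
    """A UTC timestamp offset from the fixture epoch."""
    return T0 + timedelta(days=days, hours=hours)


@pytest.fixture
def profile_factory():
    def make(
        patient_id: str = "P0001",
        personal_best: float | None = 500.0,
        with_controller: bool = True,
        requires_pef: bool = False,
        **kwargs,
    ) -> PatientProfile:
        meds = [Medication("salbutamol", MedClass.RELIEVER, "PRN")]
        if with_controller:
            meds.insert(0, Medication("budesonide", MedClass.CONTROLLER, "BID"))
        return PatientProfile(
            patient_id=patient_id,
            enrollment=T0,
            personal_best_pef=personal_best,
            medications=tuple(meds),
            action_plan=ActionPlan.from_texts(requires_pef=requires_pef),
            **kwargs,
        )

    return make
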