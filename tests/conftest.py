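import numpy as np
import pytest

from whmt import (
    DiagramCalibration,
    ParticipantRecord,
    Placement,
    Thresholds,
)


@pytest.fixture
def cal_emot():
    return DiagramCalibration.emotional_default()


@pytest.fixture
def cal_phys():
    return DiagramCalibration.physical_default()


@pytest.fixture
def th():
    return Thresholds()


def make_record(
    emotional_radii: dict[str, float],
    physical_radii: dict[str, float] | None = None,
    participant_id: str = "p0",
    age: float = 30.0,
    gender: str = "female",
    romantic_status: str = "married_engaged",
    parental_status: str = "no_child",
    angles: dict[str, float] | None = None,
) -> ParticipantRecord:
    """Build a record from per-role radii (angles default to 0 = due east)."""
    physical_radii = physical_radii if physical_radii is not None else {
        r: 100.0 for r in emotional_radii
    }
    angles = angles or {}

    def place(role, r, kind):
        a = angles.get(role, 0.0)
        return Placement(role, r * np.cos(a), r * np.sin(a), kind)

    return ParticipantRecord(
        participant_id=participant_id,
        age=age,
        gender=gender,
        romantic_status=romantic_status,
        parental_status=parental_status,
        emotional=[place(r, v, "emotional") for r, v in emotional_radii.items()],
        physical=[place(r, v, "physical") for r, v in physical_radii.items()],
    )
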