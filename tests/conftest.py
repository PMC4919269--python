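import numpy as np
import pytest

from renalpet import (
    CONTROL_INPUT,
    DEFAULT_PRESETS,
    FrameSchedule,
    GroupPreset,
    InputFunctionModel,
    SubjectRecord,
    TimeActivityCurve,
)
from renalpet.phantom import PhantomGeometry


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def control_input() -> InputFunctionModel:
    return CONTROL_INPUT


@pytest.fixture(scope="session")
def subject() -> SubjectRecord:
    return SubjectRecord("s-01", "wt", body_weight_g=20.0, injected_dose_kBq=7700.0)


def noiseless(preset_name: str) -> GroupPreset:
    """A preset with measurement noise switched off."""
    p = DEFAULT_PRESETS[preset_name]
    return GroupPreset(p.name, p.n_default, p.true_K1, p.true_k2, p.plasma_scale, 0.0)


@pytest.fixture(scope="session")
def small_geometry() -> PhantomGeometry:
    """Compact phantom grid for fast imaging tests (organs scaled down)."""
    return PhantomGeometry(
        shape=(40, 40, 64),
        heart_center=(20.0, 20.0, 48.0),
        heart_semiaxes=(10.0, 10.0, 11.0),
        liver_center=(20.0, 20.0, 30.0),
        liver_semiaxes=(10.0, 8.0, 5.0),
        kidney_l_center=(9.0, 20.0, 16.0),
        kidney_r_center=(31.0, 20.0, 16.0),
        kidney_radius=6.0,
        kidney_notch_offset=4.0,
        bladder_center=(20.0, 20.0, 5.0),
        bladder_radius=4.0,
    )


@pytest.fixture()
def constant_tac(schedule) -> TimeActivityCurve:
    return TimeActivityCurve(schedule, np.full(schedule.count, 2.0), region_label="flat")
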