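import pytest

from vgait import AgentSkill, ControllerConstants, ParticipantModel


@pytest.fixture
def constants():
    return ControllerConstants()


@pytest.fixture
def participant():
    """1.80 m participant: sl_opt 0.69966, sl_max 1.04949, sl_min 0.2623725."""
    return ParticipantModel.from_body_height(1.80)


@pytest.fixture
def perfect_skill():
    """Noiseless agent that lands every step exactly on target."""
    return AgentSkill(
        thrust_sd=0.0,
        shift_noise_sd=0.0,
        shift_hold_reliability=1.0,
        trunk_sd=0.0,
        seed=1,
    )
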