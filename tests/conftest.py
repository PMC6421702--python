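import pytest

from aemh_triage.risk_detection import RiskProfile, ScreeningQuestion
from aemh_triage.trial_simulator import DesignConfig, RespondentModel, generate_trial


@pytest.fixture
def profile():
    """A generic self-harm-flavoured profile with a questionnaire threshold."""
    return RiskProfile(
        risk_name="self_harm",
        lexicon=("end my life", "hurt myself", "no way out"),
        screening_questions=(
            ScreeningQuestion("q_sleep", "How are you sleeping?", ("barely at all",)),
            ScreeningQuestion("q_hopeless", "Do you feel hopeless?", ("often", "always")),
            ScreeningQuestion("q_safe", "Do you feel safe at the moment?", ("no",)),
        ),
        questionnaire_id="risk_scale",
        questionnaire_threshold=10.0,
    )


@pytest.fixture
def dsp_profile():
    """A profile without questionnaire: step 2 falls back to the DSP rule."""
    return RiskProfile(
        risk_name="sleep_problems",
        lexicon=("cannot sleep", "awake all night"),
        screening_questions=(
            ScreeningQuestion("q_sleep", "How are you sleeping?", ("barely at all",)),
        ),
    )


@pytest.fixture(scope="session")
def default_trial():
    """One default-condition synthetic trial, shared across read-only tests."""
    return generate_trial(DesignConfig(), RespondentModel(), seed=20_260_923)
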