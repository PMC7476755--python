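import numpy as np
import pandas as pd
import pytest

from toj import observer, preprocess


@pytest.fixture(scope="session")
def design():
    return observer.default_design()


@pytest.fixture(scope="session")
def participant_trials(design):
    """One complete simulated session (320 trials), fixed seed."""
    params = observer.ObserverParams(pss=-40.0, sigma=90.0, lapse=0.02)
    return observer.simulate_participant(
        params, design, 123, participant_id="CC01", group="CC"
    )


@pytest.fixture(scope="session")
def coded_trials(participant_trials):
    return preprocess.recode(participant_trials)


@pytest.fixture(scope="session")
def small_study():
    """Two groups x 5 participants with opposite PSS, cheap to analyze."""
    spec = observer.StudySpec(
        groups=(
            observer.GroupSpec("CC", 5, pss_mean=-40.0, pss_sd=20.0),
            observer.GroupSpec("MCC", 5, pss_mean=40.0, pss_sd=20.0),
        ),
        fraction_experimenter_entered=0.02,
    )
    return observer.simulate_study(spec, 99)


def make_trials(rows):
    """Hand-built trial table from (pid, left, right, soa, resp, rt, exp) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "modality_left",
            "modality_right",
            "soa_side",
            "response_side",
            "rt",
            "experimenter_entered",
        ],
    ).assign(group="other", experiment="visual-auditory", block=0)


@pytest.fixture
def trial_builder():
    return make_trials
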