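import numpy as np
import pandas as pd
import pytest

from emotrans.data import EmotionState, StudyDataset, standardize
from emotrans.designs import SIX_STATES, STUDY_DESIGNS
from emotrans.simulate import EFFECTS_OFF, EFFECTS_ON, SyntheticConfig, generate_study


@pytest.fixture
def six_states():
    return STUDY_DESIGNS[5].emotion_set()


@pytest.fixture
def seven_states():
    return STUDY_DESIGNS[0].emotion_set()


def make_dataset(vectors, states, target="self", loneliness=None, include_same_state=False,
                 study_id="toy"):
    """Build a StudyDataset from per-participant rating vectors.

    ``vectors``: dict participant_id -> sequence of ratings aligned with the
    enumerated transition order.
    """
    from emotrans.data import enumerate_transitions

    transitions = enumerate_transitions(states, include_same_state)
    rows = []
    for pid, vec in vectors.items():
        assert len(vec) == len(transitions)
        for t, v in zip(transitions, vec):
            rows.append((pid, target, t.from_state.label, t.to_state.label, float(v)))
    ratings = pd.DataFrame(
        rows, columns=["participant_id", "target", "from_state", "to_state", "rating"]
    )
    pids = list(vectors)
    if loneliness is None:
        loneliness = np.arange(len(pids), dtype=float) + 10.0
    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "loneliness_raw": loneliness,
            "loneliness_z": standardize(loneliness),
            "completion_fraction": 1.0,
        }
    )
    return StudyDataset(
        study_id=study_id,
        emotion_set=list(states),
        include_same_state=include_same_state,
        ratings=ratings,
        participants=participants,
    ).validate()


@pytest.fixture
def null_study(six_states):
    cfg = SyntheticConfig(
        "null", six_states, n_participants=40, include_same_state=False,
        seed=7, **EFFECTS_OFF,
    )
    return generate_study(cfg)


@pytest.fixture
def effects_study(six_states):
    cfg = SyntheticConfig(
        "planted", six_states, n_participants=120, include_same_state=False,
        seed=7, **EFFECTS_ON,
    )
    return generate_study(cfg)
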