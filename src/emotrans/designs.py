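"""Bundled multi-study design descriptions.

Seven study designs covering the variants of the emotion-transition task:
MTurk/undergraduate seven-state designs with same-state transitions, a
fifteen-state subset design, and six-state designs without same-state
transitions, one of which collected no comparable other-target ratings.
Sample sizes and loneliness-score moments are the published per-study
values; they parameterize the synthetic suite and the design-count checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .data import DEFAULT_VALENCE_MAP, EmotionState, Valence

__all__ = ["StudyDesign", "STUDY_DESIGNS", "total_n", "SEVEN_STATES", "SIX_STATES"]

SEVEN_STATES = ["anxious", "calm", "happy", "irritable", "sad", "sluggish", "full of thought"]
SEVEN_STATES_ALERT = ["anxious", "calm", "happy", "irritable", "sad", "sluggish", "alert"]
SIX_STATES = ["anxious", "sad", "amused", "satisfied", "hopeful", "content"]

# Fifteen-state design: the authoritative valence assignment is not bundled,
# so the synthetic stand-in uses an explicit map of its own.
FIFTEEN_STATES = {
    "assertive": Valence.POSITIVE,
    "confident": Valence.POSITIVE,
    "grouchy": Valence.NEGATIVE,
    "sad": Valence.NEGATIVE,
    "unrestrained": Valence.NEUTRAL,
    "bold": Valence.POSITIVE,
    "irritable": Valence.NEGATIVE,
    "lively": Valence.POSITIVE,
    "nervous": Valence.NEGATIVE,
    "talkative": Valence.NEUTRAL,
    "contempt": Valence.NEGATIVE,
    "disgust": Valence.NEGATIVE,
    "embarrassment": Valence.NEGATIVE,
    "love": Valence.POSITIVE,
    "satisfaction": Valence.POSITIVE,
}


@dataclass(frozen=True)
class StudyDesign:
    study_id: str
    n_participants: int
    emotion_labels: tuple[str, ...]
    include_same_state: bool
    has_other_target: bool
    loneliness_mean: float
    loneliness_sd: float
    valence_override: dict = field(default_factory=dict)

    def emotion_set(self) -> list[EmotionState]:
        out = []
        for label in self.emotion_labels:
            if label in self.valence_override:
                out.append(EmotionState(label, self.valence_override[label]))
            else:
                out.append(EmotionState(label, DEFAULT_VALENCE_MAP[label]))
        return out


STUDY_DESIGNS: list[StudyDesign] = [
    StudyDesign("study1", 113, tuple(SEVEN_STATES), True, True, 19.4, 13.76),
    StudyDesign("study2", 185, tuple(SEVEN_STATES), True, True, 23.23, 13.53),
    StudyDesign("study3", 376, tuple(SEVEN_STATES), True, True, 19.62, 9.88),
    StudyDesign(
        "study4", 91, tuple(FIFTEEN_STATES), True, True, 23.01, 9.83,
        valence_override=dict(FIFTEEN_STATES),
    ),
    StudyDesign("study5", 68, tuple(SEVEN_STATES_ALERT), True, True, 16.97, 11.45),
    StudyDesign("study6", 41, tuple(SIX_STATES), False, True, 19.27, 10.54),
    StudyDesign("study7", 856, tuple(SIX_STATES), False, False, 24.51, 12.50),
]


def total_n() -> int:
    """Pooled sample size across the seven bundled designs."""
    return sum(d.n_participants for d in STUDY_DESIGNS)
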