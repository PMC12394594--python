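"""Synthetic multi-study generator with known, recoverable effect structure.

The generative model is the artifact's own (the analyses assume no
particular data-generating process); its knobs plant the qualitative
patterns the analyses are built to detect, so every downstream stage can be
validated by parameter and sign recovery:

* ``atypicality_gain a`` — lonely participants drift from the group norm in
  participant-specific random directions (idiosyncrasy, not a shared bias);
* ``anchoring_intercept/slope w0, w1`` — other-ratings blend the
  participant's own self-ratings with the norm, with lonelier participants
  anchoring less when ``w1 > 0``;
* ``volatility_gain m`` — lonelier participants rate cross-valence
  transitions of others as more likely and valence persistence as less
  likely;
* ``anti_positivity_gain c`` — lonelier participants see their own
  positive states as fragile (PP down, PN up);
* ``compression_gain kappa`` — lonelier participants give less variable
  ratings (a low-confidence response style);
* ``noise_sd sigma`` — i.i.d. Gaussian rating noise, truncated to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import (
    EmotionState,
    StudyDataset,
    Target,
    ValenceCategory,
    ValidationError,
    classify_transition,
    enumerate_transitions,
    standardize,
)
from .designs import STUDY_DESIGNS, StudyDesign

__all__ = ["SyntheticConfig", "generate_study", "generate_multistudy", "default_suite"]

#: Base likelihood (percent) per endpoint-valence category; same-state pairs
#: get their own persistence level.  Plausible persistence>switching
#: structure; free parameters of the generator.
DEFAULT_BASE_MATRIX = {
    "same_state": 65.0,
    "PP": 60.0,
    "NN": 50.0,
    "PN": 30.0,
    "NP": 35.0,
    "NEUTRAL_INVOLVED": 45.0,
}


@dataclass
class SyntheticConfig:
    study_id: str
    emotion_set: list[EmotionState]
    n_participants: int = 100
    include_same_state: bool = True
    has_other_target: bool = True
    base_matrix_spec: dict = field(default_factory=lambda: dict(DEFAULT_BASE_MATRIX))
    loneliness_mean: float = 20.0
    loneliness_sd: float = 12.0
    atypicality_gain: float = 0.0
    other_atypicality_gain: float | None = None
    anchoring_intercept: float = 1.0
    anchoring_slope: float = 0.0
    volatility_gain: float = 0.0
    anti_positivity_gain: float = 0.0
    compression_gain: float = 0.0
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_participants < 3:
            raise ValidationError("n_participants must be >= 3")
        if self.atypicality_gain < 0 or self.compression_gain < 0:
            raise ValidationError("atypicality_gain and compression_gain must be >= 0")
        for key, val in self.base_matrix_spec.items():
            if not (0.0 <= float(val) <= 100.0):
                raise ValidationError(f"base likelihood {key}={val} outside [0, 100]")
        for name in (
            "atypicality_gain", "anchoring_intercept", "anchoring_slope",
            "volatility_gain", "anti_positivity_gain", "compression_gain", "noise_sd",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["emotion_set"] = [
            {"label": s.label, "valence": s.valence.value} for s in self.emotion_set
        ]
        return d


def _compress(values: np.ndarray, kappa: float, lz: float) -> np.ndarray:
    mu = values.mean()
    return mu + (values - mu) * np.exp(-kappa * lz)


def generate_study(config: SyntheticConfig) -> StudyDataset:
    """Draw one study from the generative model; same seed, same output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    states = config.emotion_set
    vmap = {s.label: s.valence for s in states}
    transitions = enumerate_transitions(states, config.include_same_state)
    n_t = len(transitions)

    cats = [classify_transition(t, vmap) for t in transitions]
    base = np.array(
        [
            config.base_matrix_spec["same_state"]
            if t.same_state and "same_state" in config.base_matrix_spec
            else config.base_matrix_spec[c.value]
            for t, c in zip(transitions, cats)
        ],
        dtype=float,
    )
    # Sign vectors for the planted effects.
    anti_pos = np.array(
        [1.0 if c == ValenceCategory.PN else -1.0 if c == ValenceCategory.PP else 0.0
         for c in cats]
    )
    vol = np.array(
        [
            1.0 if c in (ValenceCategory.PN, ValenceCategory.NP)
            else -1.0 if c in (ValenceCategory.PP, ValenceCategory.NN)
            else 0.0
            for c in cats
        ]
    )

    raw = np.clip(
        np.round(rng.normal(config.loneliness_mean, config.loneliness_sd, config.n_participants)),
        0, 60,
    )
    if np.std(raw, ddof=1) == 0:  # pathological draw; nudge one participant
        raw[0] = min(raw[0] + 1, 60) if raw[0] < 60 else raw[0] - 1
    lz = standardize(raw)

    other_gain = (
        config.atypicality_gain
        if config.other_atypicality_gain is None
        else config.other_atypicality_gain
    )

    rows = []
    n_trunc = 0
    n_total = 0
    for i in range(config.n_participants):
        pid = f"p{i + 1:04d}"
        direction = rng.standard_normal(n_t)
        direction /= np.linalg.norm(direction)
        eps = rng.normal(0.0, config.noise_sd, n_t)
        # Compression acts on the structured expectation, not the trial
        # noise: a flat-responding participant still jitters trial to
        # trial, and compressing the noise as well would shrink lonely
        # participants' rating variance so hard that regressions on their
        # ratings steepen mechanically, swamping the planted accuracy
        # deficit.
        self_r = _compress(
            base
            + config.atypicality_gain * max(lz[i], 0.0) * direction * 100.0
            + config.anti_positivity_gain * lz[i] * anti_pos,
            config.compression_gain, lz[i],
        ) + eps
        n_trunc += int(((self_r < 0) | (self_r > 100)).sum())
        n_total += n_t
        self_r = np.clip(self_r, 0.0, 100.0)
        for t, v in zip(transitions, np.round(self_r, 3)):
            rows.append((pid, Target.SELF.value, t.from_state.label, t.to_state.label, v))

        if config.has_other_target:
            w = expit(config.anchoring_intercept - config.anchoring_slope * lz[i])
            eps2 = rng.normal(0.0, config.noise_sd, n_t)
            # Lonely participants' model of others is itself idiosyncratic:
            # without this term, blending toward the noiseless norm would
            # make them *more* normative and accurate, the opposite of the
            # patterns the analyses must be able to recover.
            direction2 = rng.standard_normal(n_t)
            direction2 /= np.linalg.norm(direction2)
            norm_view = (
                base
                + config.volatility_gain * lz[i] * vol
                + other_gain * max(lz[i], 0.0) * direction2 * 100.0
            )
            other_r = _compress(
                w * self_r + (1.0 - w) * norm_view,
                config.compression_gain, lz[i],
            ) + eps2
            n_trunc += int(((other_r < 0) | (other_r > 100)).sum())
            n_total += n_t
            other_r = np.clip(other_r, 0.0, 100.0)
            for t, v in zip(transitions, np.round(other_r, 3)):
                rows.append((pid, Target.OTHER.value, t.from_state.label, t.to_state.label, v))

    ratings = pd.DataFrame(
        rows, columns=["participant_id", "target", "from_state", "to_state", "rating"]
    )
    participants = pd.DataFrame(
        {
            "participant_id": [f"p{i + 1:04d}" for i in range(config.n_participants)],
            "loneliness_raw": raw,
            "loneliness_z": lz,
            "completion_fraction": 1.0,
        }
    )
    ds = StudyDataset(
        study_id=config.study_id,
        emotion_set=list(states),
        include_same_state=config.include_same_state,
        ratings=ratings,
        participants=participants,
        meta={
            "synthetic": True,
            "config": config.to_dict(),
            "truncation_fraction": n_trunc / max(n_total, 1),
        },
    )
    return ds.validate()


def generate_multistudy(configs: list[SyntheticConfig]) -> list[StudyDataset]:
    """Independent datasets, one per config; study ids must be unique."""
    if not configs:
        raise ValidationError("at least one config required")
    ids = [c.study_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate study_id in {ids}")
    return [generate_study(c) for c in configs]


# Effect parameters that plant every reported qualitative direction.
EFFECTS_ON = dict(
    atypicality_gain=0.4,
    other_atypicality_gain=0.9,
    anchoring_intercept=0.5,
    anchoring_slope=0.5,
    volatility_gain=3.0,
    anti_positivity_gain=6.0,
    compression_gain=0.06,
    noise_sd=8.0,
)

EFFECTS_OFF = dict(
    atypicality_gain=0.0,
    other_atypicality_gain=0.0,
    anchoring_intercept=0.5,
    anchoring_slope=0.0,
    volatility_gain=0.0,
    anti_positivity_gain=0.0,
    compression_gain=0.0,
    noise_sd=8.0,
)


def default_suite(
    master_seed: int,
    effects: bool = True,
    n_scale: float = 1.0,
    designs: list[StudyDesign] | None = None,
) -> list[SyntheticConfig]:
    """Configs mirroring the seven bundled designs.

    Per-study seeds are offset deterministically from ``master_seed``;
    ``n_scale`` shrinks sample sizes for fast simulation studies (floor 12).
    """
    designs = STUDY_DESIGNS if designs is None else designs
    params = EFFECTS_ON if effects else EFFECTS_OFF
    configs = []
    for j, d in enumerate(designs):
        configs.append(
            SyntheticConfig(
                study_id=d.study_id,
                emotion_set=d.emotion_set(),
                n_participants=max(12, int(round(d.n_participants * n_scale))),
                include_same_state=d.include_same_state,
                has_other_target=d.has_other_target,
                loneliness_mean=d.loneliness_mean,
                loneliness_sd=d.loneliness_sd,
                seed=master_seed * 1000 + j,
                **params,
            )
        )
    return configs
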