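"""Core domain types, I/O, loneliness scoring, and transition utilities.

The basic unit of data is one participant's 0-100 likelihood rating of a
directed emotion-state transition for a target (self or other).  A study
bundles an emotion set, a long-format ratings table, and per-participant
loneliness scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Valence",
    "Target",
    "ValenceCategory",
    "EmotionState",
    "TransitionPair",
    "RatingRecord",
    "ParticipantProfile",
    "StudyConfig",
    "StudyDataset",
    "SchemaError",
    "ValidationError",
    "DEFAULT_REVERSE_KEYS",
    "DEFAULT_VALENCE_MAP",
    "score_ucla",
    "enumerate_transitions",
    "classify_transition",
    "standardize",
    "read_study",
    "write_study",
]


class SchemaError(ValueError):
    """A file does not conform to the documented column schema."""


class ValidationError(ValueError):
    """Data violate a domain invariant (bounds, uniqueness, membership)."""


class Valence(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEUTRAL = "neutral"


class Target(str, Enum):
    SELF = "self"
    OTHER = "other"


class ValenceCategory(str, Enum):
    """Endpoint-valence class of a directed transition."""

    PP = "PP"
    PN = "PN"
    NP = "NP"
    NN = "NN"
    NEUTRAL_INVOLVED = "NEUTRAL_INVOLVED"


#: Reverse-worded items of the standard 20-item loneliness scale (1-based).
DEFAULT_REVERSE_KEYS = frozenset({1, 5, 6, 9, 10, 15, 16, 19, 20})

#: Valence assignments for the emotion labels used across the bundled study
#: designs.  Fifteen-state designs need a user-supplied map.
DEFAULT_VALENCE_MAP: dict[str, Valence] = {
    "happy": Valence.POSITIVE,
    "calm": Valence.POSITIVE,
    "amused": Valence.POSITIVE,
    "satisfied": Valence.POSITIVE,
    "hopeful": Valence.POSITIVE,
    "content": Valence.POSITIVE,
    "anxious": Valence.NEGATIVE,
    "sad": Valence.NEGATIVE,
    "irritable": Valence.NEGATIVE,
    "sluggish": Valence.NEGATIVE,
    "full of thought": Valence.NEUTRAL,
    "alert": Valence.NEUTRAL,
}


@dataclass(frozen=True)
class EmotionState:
    label: str
    valence: Valence

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("emotion label must be non-empty")
        object.__setattr__(self, "valence", Valence(self.valence))


@dataclass(frozen=True)
class TransitionPair:
    """Directed pair of emotion states; A->B is distinct from B->A."""

    from_state: EmotionState
    to_state: EmotionState

    @property
    def same_state(self) -> bool:
        return self.from_state.label == self.to_state.label

    @property
    def key(self) -> tuple[str, str]:
        return (self.from_state.label, self.to_state.label)


@dataclass(frozen=True)
class RatingRecord:
    participant_id: str
    target: Target
    transition: TransitionPair
    rating: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rating <= 100.0):
            raise ValidationError(
                f"rating {self.rating} outside [0, 100] for participant "
                f"{self.participant_id}, transition {self.transition.key}"
            )


@dataclass
class ParticipantProfile:
    participant_id: str
    loneliness_raw: float
    loneliness_z: float | None = None
    completion_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.loneliness_raw <= 60):
            raise ValidationError(
                f"loneliness_raw {self.loneliness_raw} outside [0, 60] "
                f"for participant {self.participant_id}"
            )


@dataclass
class StudyConfig:
    """Per-study design description used when reading raw CSV files."""

    emotion_set: list[EmotionState]
    include_same_state: bool = True
    reverse_keys: frozenset[int] = DEFAULT_REVERSE_KEYS
    completion_threshold: float = 0.5
    prorate_incomplete: bool = False

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        states = [EmotionState(s["label"], Valence(s["valence"])) for s in d["emotion_set"]]
        return cls(
            emotion_set=states,
            include_same_state=bool(d.get("include_same_state", True)),
            reverse_keys=frozenset(d.get("reverse_keys", DEFAULT_REVERSE_KEYS)),
            completion_threshold=float(d.get("completion_threshold", 0.5)),
            prorate_incomplete=bool(d.get("prorate_incomplete", False)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in {".yaml", ".yml"}:
                return cls.from_dict(yaml.safe_load(fh))
            return cls.from_dict(json.load(fh))


RATINGS_COLUMNS = ["study_id", "participant_id", "target", "from_state", "to_state", "rating"]


@dataclass
class StudyDataset:
    """One study: emotion set, long-format ratings, participant profiles.

    ``ratings`` has columns ``participant_id, target, from_state, to_state,
    rating``; ``participants`` has ``participant_id, loneliness_raw,
    loneliness_z, completion_fraction``.
    """

    study_id: str
    emotion_set: list[EmotionState]
    include_same_state: bool
    ratings: pd.DataFrame
    participants: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def targets_present(self) -> set[str]:
        return set(self.ratings["target"].unique())

    @property
    def valence_map(self) -> dict[str, Valence]:
        return {s.label: s.valence for s in self.emotion_set}

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def validate(self) -> "StudyDataset":
        labels = [s.label for s in self.emotion_set]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate emotion labels in study {self.study_id}")
        r = self.ratings
        missing = set(RATINGS_COLUMNS[1:]) - set(r.columns)
        if missing:
            raise SchemaError(f"ratings table missing columns {sorted(missing)}")
        bad = r[(r["rating"] < 0) | (r["rating"] > 100) | r["rating"].isna()]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"rating {row['rating']} outside [0, 100] at participant "
                f"{row['participant_id']} transition "
                f"({row['from_state']} -> {row['to_state']})"
            )
        known = set(labels)
        for col in ("from_state", "to_state"):
            unknown = set(r[col].unique()) - known
            if unknown:
                raise ValidationError(
                    f"unknown emotion label(s) {sorted(unknown)} in column {col}"
                )
        if not self.include_same_state and (r["from_state"] == r["to_state"]).any():
            raise ValidationError(
                f"same-state ratings present but include_same_state=False in {self.study_id}"
            )
        dup = r.duplicated(subset=["participant_id", "target", "from_state", "to_state"])
        if dup.any():
            raise ValidationError(
                f"duplicate (participant, target, transition) rows in {self.study_id}"
            )
        orphans = set(r["participant_id"]) - set(self.participants["participant_id"])
        if orphans:
            raise ValidationError(
                f"ratings reference participants without profiles: {sorted(orphans)[:5]}"
            )
        return self

    def loneliness_z_by_id(self) -> pd.Series:
        return self.participants.set_index("participant_id")["loneliness_z"]


def score_ucla(
    responses: Sequence[int],
    reverse_keys: Iterable[int] = DEFAULT_REVERSE_KEYS,
) -> int:
    """Sum score of the 20-item loneliness scale (0-3 responses, 1-based keys).

    Reverse-keyed items contribute ``3 - x``; the score ranges over [0, 60].
    """
    responses = list(responses)
    if len(responses) != 20:
        raise ValidationError(f"expected 20 responses, got {len(responses)}")
    keys = set(reverse_keys)
    if not keys <= set(range(1, 21)):
        raise ValidationError(f"reverse keys must be within 1..20, got {sorted(keys)}")
    total = 0
    for i, x in enumerate(responses, start=1):
        if x not in (0, 1, 2, 3):
            raise ValidationError(f"item {i} response {x!r} not in {{0,1,2,3}}")
        total += (3 - x) if i in keys else x
    return total


def enumerate_transitions(
    states: Sequence[EmotionState], include_same_state: bool
) -> list[TransitionPair]:
    """All ordered state pairs in from-major, to-minor input order.

    Returns ``n**2`` pairs with same-state pairs included, ``n*(n-1)``
    without.
    """
    labels = [s.label for s in states]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate emotion labels: {labels}")
    if not states:
        raise ValidationError("at least one state required")
    pairs = []
    for a in states:
        for b in states:
            if a.label == b.label and not include_same_state:
                continue
            pairs.append(TransitionPair(a, b))
    return pairs


def classify_transition(
    pair: TransitionPair | tuple[str, str],
    valence_map: Mapping[str, Valence],
) -> ValenceCategory:
    """Endpoint-valence category; any neutral endpoint yields NEUTRAL_INVOLVED."""
    if isinstance(pair, TransitionPair):
        a, b = pair.key
    else:
        a, b = pair
    for label in (a, b):
        if label not in valence_map:
            raise ValidationError(f"emotion label {label!r} missing from valence map")
    va, vb = Valence(valence_map[a]), Valence(valence_map[b])
    if Valence.NEUTRAL in (va, vb):
        return ValenceCategory.NEUTRAL_INVOLVED
    code = ("P" if va == Valence.POSITIVE else "N") + ("P" if vb == Valence.POSITIVE else "N")
    return ValenceCategory(code)


def standardize(values: Sequence[float]) -> np.ndarray:
    """Z-score with the sample SD (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("standardize requires at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError("zero variance: skip standardization for this variable")
    return (x - x.mean()) / sd


def _score_participants(df: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    item_cols = [f"item_{i}" for i in range(1, 21)]
    out = df[["participant_id"]].copy()
    out["completion_fraction"] = (
        df["completion_fraction"].astype(float) if "completion_fraction" in df.columns else 1.0
    )
    if set(item_cols) <= set(df.columns):
        raws = []
        keep = []
        for idx, row in df.iterrows():
            items = row[item_cols]
            if items.isna().any():
                if config.prorate_incomplete and items.notna().sum() >= 10:
                    present = items.dropna()
                    scored = sum(
                        (3 - int(v)) if (int(c.split("_")[1]) in config.reverse_keys) else int(v)
                        for c, v in present.items()
                    )
                    raws.append(round(scored * 20 / len(present)))
                    keep.append(idx)
                else:
                    logger.info("dropping participant %s: incomplete scale", row["participant_id"])
                continue
            raws.append(score_ucla([int(v) for v in items], config.reverse_keys))
            keep.append(idx)
        out = out.loc[keep].copy()
        out["loneliness_raw"] = raws
    elif "loneliness_total" in df.columns:
        out["loneliness_raw"] = df["loneliness_total"].astype(float)
    else:
        raise SchemaError("participants file needs item_1..item_20 or loneliness_total")
    return out


def read_study(
    ratings_path: str | Path,
    participants_path: str | Path,
    config: StudyConfig,
    study_id: str | None = None,
) -> StudyDataset:
    """Load and validate one study from the long-format CSV pair.

    Participants below the completion threshold are dropped (and logged);
    loneliness is z-scored across the retained participants.
    """
    # Only empty cells are missing; labels like "null" stay literal strings.
    ratings = pd.read_csv(ratings_path, keep_default_na=False, na_values=[""])
    missing = set(RATINGS_COLUMNS) - set(ratings.columns)
    if missing:
        raise SchemaError(f"ratings CSV missing columns {sorted(missing)}")
    parts_raw = pd.read_csv(participants_path, keep_default_na=False, na_values=[""])
    if "participant_id" not in parts_raw.columns:
        raise SchemaError("participants CSV missing participant_id column")
    if study_id is None:
        ids = ratings["study_id"].unique()
        if len(ids) != 1:
            raise ValidationError(f"expected a single study_id, found {sorted(ids)}")
        study_id = str(ids[0])

    parts = _score_participants(parts_raw, config)
    below = parts["completion_fraction"] < config.completion_threshold
    if below.any():
        logger.info(
            "study %s: dropping %d participant(s) below completion threshold %.2f",
            study_id, int(below.sum()), config.completion_threshold,
        )
        parts = parts[~below]
    bad = parts[(parts["loneliness_raw"] < 0) | (parts["loneliness_raw"] > 60)]
    if len(bad):
        raise ValidationError(
            f"loneliness score outside [0, 60] for participant "
            f"{bad.iloc[0]['participant_id']}"
        )
    parts = parts.reset_index(drop=True)
    parts["loneliness_z"] = standardize(parts["loneliness_raw"].to_numpy())

    keep_ids = set(parts["participant_id"])
    ratings = ratings[ratings["participant_id"].isin(keep_ids)].reset_index(drop=True)
    ratings = ratings[RATINGS_COLUMNS[1:]].copy()
    ratings["participant_id"] = ratings["participant_id"].astype(str)
    parts["participant_id"] = parts["participant_id"].astype(str)

    ds = StudyDataset(
        study_id=study_id,
        emotion_set=list(config.emotion_set),
        include_same_state=config.include_same_state,
        ratings=ratings,
        participants=parts[
            ["participant_id", "loneliness_raw", "loneliness_z", "completion_fraction"]
        ],
    )
    return ds.validate()


def write_study(dataset: StudyDataset, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a dataset back to the CSV pair; inverse of :func:`read_study`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rpath = out / f"{dataset.study_id}_ratings.csv"
    ppath = out / f"{dataset.study_id}_participants.csv"
    r = dataset.ratings.copy()
    r.insert(0, "study_id", dataset.study_id)
    r.to_csv(rpath, index=False)
    p = dataset.participants.copy()
    p.insert(0, "study_id", dataset.study_id)
    p = p.rename(columns={"loneliness_raw": "loneliness_total"})
    p[["study_id", "participant_id", "loneliness_total", "completion_fraction"]].to_csv(
        ppath, index=False
    )
    return rpath, ppath
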