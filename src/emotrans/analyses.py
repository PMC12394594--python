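"""Study-level analyses, each yielding effect sizes for meta-analytic pooling.

Five families: ground-truth prediction accuracy, self-anchoring, valence
simple slopes (other and self targets), and rating-SD confidence.  The
mixed models use crossed random intercepts for participant, from-state,
and to-state; outcome and continuous predictors are z-scored within study
so coefficients are on a standardized scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    StudyDataset,
    Target,
    ValenceCategory,
    ValidationError,
    classify_transition,
    standardize,
)
from .lmm import LMMFit, LMMSpec, fit_lmm, simple_slopes
from .meta import EffectSize, fisher_z

logger = logging.getLogger(__name__)

__all__ = [
    "build_ground_truth",
    "accuracy_effect",
    "anchoring_effect",
    "valence_effects",
    "confidence_effect",
]

RANDOM_FACTORS = ["participant_id", "from_state", "to_state"]


def _z(values: np.ndarray) -> np.ndarray:
    return standardize(values)


def _long_table(dataset: StudyDataset, target: str) -> pd.DataFrame:
    sub = dataset.ratings[dataset.ratings["target"] == target].copy()
    if sub.empty:
        raise ValidationError(f"study {dataset.study_id} has no target={target!r} ratings")
    lz = dataset.loneliness_z_by_id()
    sub["loneliness_z"] = sub["participant_id"].map(lz)
    return sub


def build_ground_truth(dataset: StudyDataset) -> pd.Series:
    """Per-transition mean of self ratings across all participants.

    Indexed by ``(from_state, to_state)``; a transition nobody rated is
    simply absent.
    """
    self_rows = dataset.ratings[dataset.ratings["target"] == Target.SELF.value]
    if self_rows.empty:
        raise ValidationError(f"study {dataset.study_id} has no self-target ratings")
    gt = self_rows.groupby(["from_state", "to_state"])["rating"].mean()
    gt.name = "ground_truth"
    return gt


def accuracy_effect(dataset: StudyDataset) -> EffectSize:
    """Loneliness moderation of how well other-ratings track the ground truth.

    Mixed model: ground truth ~ other_rating_z * loneliness_z with the
    standard crossed random intercepts; the interaction coefficient is the
    effect (negative = lonelier participants' predictions align less).
    """
    if Target.OTHER.value not in dataset.targets_present:
        raise ValidationError(
            f"study {dataset.study_id} lacks other-target ratings; accuracy skipped"
        )
    tab = _long_table(dataset, Target.OTHER.value)
    gt = build_ground_truth(dataset)
    tab = tab.join(gt, on=["from_state", "to_state"], how="inner").dropna(
        subset=["ground_truth", "rating", "loneliness_z"]
    )
    tab["gt_z"] = _z(tab["ground_truth"].to_numpy())
    tab["other_z"] = _z(tab["rating"].to_numpy())
    spec = LMMSpec(
        outcome="gt_z",
        fixed_terms=["other_z", "loneliness_z", "other_z:loneliness_z"],
        random_intercept_factors=RANDOM_FACTORS,
    )
    fit = fit_lmm(tab, spec)
    return _interaction_effect(fit, dataset, "accuracy", "other_z:loneliness_z")


def anchoring_effect(dataset: StudyDataset) -> EffectSize:
    """Loneliness moderation of self-to-other projection.

    Mixed model: other_z ~ self_z * loneliness_z; a negative interaction
    means lonelier participants anchor less on their own ratings.
    """
    if Target.OTHER.value not in dataset.targets_present:
        raise ValidationError(
            f"study {dataset.study_id} lacks other-target ratings; anchoring skipped"
        )
    other = _long_table(dataset, Target.OTHER.value)
    self_rows = dataset.ratings[dataset.ratings["target"] == Target.SELF.value]
    self_rows = self_rows.rename(columns={"rating": "self_rating"})[
        ["participant_id", "from_state", "to_state", "self_rating"]
    ]
    tab = other.merge(self_rows, on=["participant_id", "from_state", "to_state"], how="inner")
    n_dropped = len(other) - len(tab)
    if n_dropped:
        logger.info(
            "study %s anchoring: dropped %d row(s) without a matching self rating",
            dataset.study_id, n_dropped,
        )
    tab = tab.dropna(subset=["rating", "self_rating", "loneliness_z"])
    tab["other_z"] = _z(tab["rating"].to_numpy())
    tab["self_z"] = _z(tab["self_rating"].to_numpy())
    spec = LMMSpec(
        outcome="other_z",
        fixed_terms=["self_z", "loneliness_z", "self_z:loneliness_z"],
        random_intercept_factors=RANDOM_FACTORS,
    )
    fit = fit_lmm(tab, spec)
    return _interaction_effect(fit, dataset, "anchoring", "self_z:loneliness_z")


def _interaction_effect(
    fit: LMMFit, dataset: StudyDataset, analysis: str, term: str
) -> EffectSize:
    return EffectSize(
        study_id=dataset.study_id,
        analysis=analysis,
        estimate=fit.coef(term),
        variance=fit.se(term) ** 2,
        n=dataset.n_participants,
        scale="beta",
    )


def valence_effects(dataset: StudyDataset, target: str) -> list[EffectSize]:
    """Loneliness simple slopes per endpoint-valence transition category.

    Neutral-involving transitions are excluded; the mixed model is
    rating_z ~ C(category) * loneliness_z with crossed random intercepts,
    and the four slopes come out of the interaction's linear combinations.
    A category absent from the design is omitted (logged).
    """
    tab = _long_table(dataset, target)
    vmap = dataset.valence_map
    tab["category"] = [
        classify_transition((f, t), vmap).value
        for f, t in zip(tab["from_state"], tab["to_state"])
    ]
    tab = tab[tab["category"] != ValenceCategory.NEUTRAL_INVOLVED.value].copy()
    present = sorted(tab["category"].unique())
    if len(present) < 2:
        raise ValidationError(
            f"study {dataset.study_id}: need >= 2 non-neutral categories, have {present}"
        )
    missing = sorted(set(c.value for c in ValenceCategory) - {"NEUTRAL_INVOLVED"} - set(present))
    if missing:
        logger.info("study %s target=%s: categories absent: %s",
                    dataset.study_id, target, missing)
    tab["rating_z"] = _z(tab["rating"].to_numpy())
    spec = LMMSpec(
        outcome="rating_z",
        fixed_terms=["C(category)", "loneliness_z", "loneliness_z:C(category)"],
        random_intercept_factors=RANDOM_FACTORS,
        references={"category": present[0]},
    )
    fit = fit_lmm(tab, spec)
    slopes = simple_slopes(fit, "loneliness_z", "category")
    out = []
    for s in slopes:
        out.append(
            EffectSize(
                study_id=dataset.study_id,
                analysis=f"slope_{s.category}_{target}",
                estimate=s.slope,
                variance=s.se**2,
                n=dataset.n_participants,
                scale="beta",
            )
        )
    return out


def confidence_effect(dataset: StudyDataset, target: str) -> EffectSize:
    """Correlation of per-participant rating SD (confidence proxy) with loneliness.

    SD uses the n-1 denominator; an all-constant responder legitimately
    scores 0.  Returned as Fisher z with variance 1/(n-3).
    """
    tab = _long_table(dataset, target)
    per = tab.groupby("participant_id")["rating"].agg(["std", "count"])
    if (per["count"] < 2).any():
        bad = per.index[per["count"] < 2].tolist()
        raise ValidationError(f"participants with < 2 ratings: {bad[:5]}")
    sds = per["std"]
    lz = dataset.loneliness_z_by_id().loc[sds.index]
    if len(sds) < 4:
        raise ValidationError("need >= 4 participants for the confidence correlation")
    if np.std(sds.to_numpy(), ddof=1) == 0:
        raise ValidationError("all participants have identical rating SDs")
    r = float(stats.pearsonr(sds.to_numpy(float), lz.to_numpy(float))[0])
    est, var = fisher_z(r, len(sds))
    return EffectSize(
        study_id=dataset.study_id,
        analysis=f"confidence_{target}",
        estimate=est,
        variance=var,
        n=len(sds),
        scale="fisher_z",
    )
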