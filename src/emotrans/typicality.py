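"""Typicality indices and Anna-Karenina intersubject similarity analysis.

A participant's typicality index is the Pearson correlation between their
vector of transition ratings and the group-average vector.  The
Anna-Karenina hypothesis says high-trait participants are idiosyncratic —
alike in being unalike — which an IS-RSA tests by correlating the pairwise
rating-similarity matrix against a trait-derived model matrix, with Mantel
permutation inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import StudyDataset, ValidationError
from .meta import EffectSize, fisher_z

logger = logging.getLogger(__name__)

__all__ = [
    "TypicalityResult",
    "SimilarityMatrix",
    "ISRSAResult",
    "rating_matrix",
    "typicality_index",
    "typicality_effect",
    "similarity_matrix",
    "ak_isrsa",
]


@dataclass
class TypicalityResult:
    indices: pd.Series  # participant_id -> index in [-1, 1]
    n_used: int
    mode: str  # "include_self" | "leave_one_out"
    target: str
    excluded: list[str]


@dataclass
class SimilarityMatrix:
    participant_ids: list[str]
    values: np.ndarray  # symmetric, unit diagonal

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.participant_ids):
            raise ValidationError("similarity matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("similarity matrix must be symmetric")
        np.fill_diagonal(self.values, 1.0)


@dataclass
class ISRSAResult:
    rho: float
    p_perm: float
    n_perm: int
    model: str
    target: str
    n: int
    seed: int

    def effect(self, study_id: str, analysis: str) -> EffectSize:
        est, var = fisher_z(self.rho, self.n)
        return EffectSize(
            study_id=study_id, analysis=analysis, estimate=est,
            variance=var, n=self.n, scale="fisher_z",
        )


def rating_matrix(dataset: StudyDataset, target: str) -> pd.DataFrame:
    """Participants x transitions matrix for one target, complete rows only.

    Columns are ``(from, to)`` keys; participants with any missing
    transition for the target are dropped (logged).  Row order is sorted
    participant id, for determinism.
    """
    sub = dataset.ratings[dataset.ratings["target"] == target]
    if sub.empty:
        raise ValidationError(f"no ratings with target={target!r}")
    wide = sub.pivot(
        index="participant_id", columns=["from_state", "to_state"], values="rating"
    )
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        logger.info("target=%s: dropped %d incomplete vector(s)", target, len(dropped))
    return complete.sort_index()


def _drop_zero_variance(wide: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    sds = wide.std(axis=1, ddof=1)
    bad = sds[(sds == 0) | sds.isna()].index.tolist()
    if bad:
        logger.warning("excluding zero-variance rating vector(s): %s", bad)
    return wide.drop(index=bad), [str(b) for b in bad]


def typicality_index(
    dataset: StudyDataset, target: str, mode: str = "include_self"
) -> TypicalityResult:
    """Per-participant correlation with the group-average rating vector.

    ``include_self`` correlates against the grand mean (the literal
    definition); ``leave_one_out`` recomputes the mean without the focal
    participant, removing the small-sample self-correlation bias.
    """
    if mode not in ("include_self", "leave_one_out"):
        raise ValidationError(f"unknown typicality mode {mode!r}")
    wide = rating_matrix(dataset, target)
    if len(wide) < 3:
        raise ValidationError(f"need >= 3 complete participants, have {len(wide)}")
    usable, excluded = _drop_zero_variance(wide)
    if usable.empty:
        raise ValidationError("no participant has a non-constant rating vector")
    # Zero-variance responders get no index but still shape the group mean.
    n = len(wide)
    mat = wide.to_numpy(float)
    grand = mat.mean(axis=0)
    out = {}
    for i, pid in enumerate(wide.index):
        if pid in excluded or str(pid) in excluded:
            continue
        ref = grand if mode == "include_self" else (grand * n - mat[i]) / (n - 1)
        if np.std(ref) == 0:
            raise ValidationError("group mean vector has zero variance")
        out[str(pid)] = float(stats.pearsonr(mat[i], ref)[0])
    return TypicalityResult(
        indices=pd.Series(out, name="typicality"),
        n_used=len(out),
        mode=mode,
        target=target,
        excluded=excluded,
    )


def typicality_effect(
    result: TypicalityResult, participants: pd.DataFrame, study_id: str
) -> EffectSize:
    """Association of the typicality index with standardized loneliness.

    Pearson r, carried as Fisher z with variance 1/(n-3).
    """
    lz = participants.set_index("participant_id")["loneliness_z"]
    common = result.indices.index.intersection(lz.index)
    if len(common) < 4:
        raise ValidationError("need >= 4 participants with index and loneliness")
    x = result.indices.loc[common].to_numpy(float)
    y = lz.loc[common].to_numpy(float)
    if np.std(y, ddof=1) == 0:
        raise ValidationError("constant loneliness: correlation undefined")
    r = float(stats.pearsonr(x, y)[0])
    est, var = fisher_z(r, len(common))
    return EffectSize(
        study_id=study_id,
        analysis=f"typicality_{result.target}",
        estimate=est,
        variance=var,
        n=len(common),
        scale="fisher_z",
    )


def similarity_matrix(dataset: StudyDataset, target: str) -> SimilarityMatrix:
    """Pairwise Pearson correlations of complete rating vectors."""
    wide, _ = _drop_zero_variance(rating_matrix(dataset, target))
    if len(wide) < 3:
        raise ValidationError(f"need >= 3 usable participants, have {len(wide)}")
    vals = np.corrcoef(wide.to_numpy(float))
    vals = 0.5 * (vals + vals.T)
    return SimilarityMatrix([str(i) for i in wide.index], vals)


def _model_matrix(lz: np.ndarray, model: str) -> np.ndarray:
    li, lj = lz[:, None], lz[None, :]
    if model == "ak_mean":
        return 0.5 * (li + lj)
    if model == "ak_min":
        return np.minimum(li, lj)
    if model == "nn":
        return -np.abs(li - lj)
    raise ValidationError(f"unknown IS-RSA model {model!r}")


def _tri_pearson_ranked(a_rank: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho between a fixed ranked vector and each row of b."""
    b_rank = stats.rankdata(b, axis=-1)
    a_c = a_rank - a_rank.mean()
    b_c = b_rank - b_rank.mean(axis=-1, keepdims=True)
    num = b_c @ a_c
    den = np.sqrt((a_c @ a_c) * (b_c**2).sum(axis=-1))
    return num / den


def ak_isrsa(
    sim: SimilarityMatrix,
    loneliness_z: np.ndarray | pd.Series,
    model: str = "ak_mean",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> ISRSAResult:
    """Mantel-style IS-RSA of the similarity matrix against a trait model.

    The statistic is the Spearman correlation between the lower triangles
    of the similarity matrix and the model matrix (``ak_mean``: pair mean
    of the trait; ``ak_min``: pair minimum; ``nn``: nearest-neighbour
    ``-|Li - Lj|``).  The two-sided p-value permutes participant labels of
    the trait vector and rebuilds the model matrix each time:
    ``p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm)``.
    """
    if seed is None:
        raise ValidationError("a seed is required for permutation inference")
    if n_perm < 100:
        raise ValidationError("n_perm < 100 gives too coarse a p-value lattice")
    lz = np.asarray(
        loneliness_z.loc[sim.participant_ids]
        if isinstance(loneliness_z, pd.Series)
        else loneliness_z,
        dtype=float,
    )
    n = len(sim.participant_ids)
    if lz.shape != (n,):
        raise ValidationError("loneliness vector not aligned with similarity matrix")
    if np.std(lz) == 0:
        raise ValidationError("constant loneliness: IS-RSA undefined")
    rows, cols = np.tril_indices(n, k=-1)
    sim_tri_rank = stats.rankdata(sim.values[rows, cols])

    def tri(mat_lz: np.ndarray) -> np.ndarray:
        m = _model_matrix(mat_lz, model)
        return m[..., rows, cols] if m.ndim > 2 else m[rows, cols]

    rho_obs = float(_tri_pearson_ranked(sim_tri_rank, tri(lz)[None, :])[0])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    lz_perm = lz[perms]  # n_perm x n
    # model matrix lower triangle for all permutations at once
    if model == "ak_mean":
        tri_perm = 0.5 * (lz_perm[:, rows] + lz_perm[:, cols])
    elif model == "ak_min":
        tri_perm = np.minimum(lz_perm[:, rows], lz_perm[:, cols])
    else:
        tri_perm = -np.abs(lz_perm[:, rows] - lz_perm[:, cols])
    rho_perm = _tri_pearson_ranked(sim_tri_rank, tri_perm)
    p = (1.0 + np.sum(np.abs(rho_perm) >= abs(rho_obs))) / (1.0 + n_perm)
    return ISRSAResult(
        rho=rho_obs, p_perm=float(p), n_perm=n_perm, model=model,
        target="", n=n, seed=seed,
    )
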