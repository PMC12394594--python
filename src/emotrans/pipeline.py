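"""End-to-end orchestration: simulate/load studies, analyze, pool, report.

Outputs are deterministic functions of the config and master seed: an
effects CSV (one row per study-level effect), a meta JSON (one pooled
result per analysis family), forest-plot CSVs, and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .analyses import (
    accuracy_effect,
    anchoring_effect,
    confidence_effect,
    valence_effects,
)
from .data import StudyConfig, StudyDataset, Target, ValidationError, read_study
from .meta import EffectSize, MetaResult, pool
from .simulate import SyntheticConfig, default_suite, generate_multistudy
from .typicality import ak_isrsa, similarity_matrix, typicality_effect, typicality_index

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_report",
           "EXPECTED_DIRECTIONS", "study_effects", "pool_effects"]

#: Reported qualitative direction per analysis family (sign of the pooled
#: estimate when the planted effects are on).
EXPECTED_DIRECTIONS = {
    "typicality_self": -1,
    "typicality_other": -1,
    "isrsa_self": -1,
    "isrsa_other": -1,
    "accuracy": -1,
    "anchoring": -1,
    "slope_PN_other": +1,
    "slope_NP_other": +1,
    "slope_PP_other": -1,
    "slope_NN_other": -1,
    "slope_PP_self": -1,
    "slope_PN_self": +1,
    "confidence_self": -1,
    "confidence_other": -1,
}


@dataclass
class PipelineConfig:
    studies: list[SyntheticConfig | dict] = field(default_factory=list)
    master_seed: int | None = None
    typicality_mode: str = "include_self"
    isrsa_model: str = "ak_mean"
    n_perm: int = 10_000
    run_typicality: bool = True
    run_isrsa: bool = True
    run_accuracy: bool = True
    run_anchoring: bool = True
    run_valence: bool = True
    run_confidence: bool = True
    out_dir: str | Path = "emotrans_out"

    def validate(self) -> "PipelineConfig":
        ids = [self._study_id(s) for s in self.studies]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate study ids: {ids}")
        any_synth = any(isinstance(s, SyntheticConfig) for s in self.studies)
        if (any_synth or self.run_isrsa) and self.master_seed is None:
            raise ValidationError(
                "master_seed is required with synthetic studies or permutation tests"
            )
        return self

    @staticmethod
    def _study_id(s) -> str:
        return s.study_id if isinstance(s, SyntheticConfig) else s["study_id"]

    def canonical_dict(self) -> dict:
        return {
            "studies": [
                s.to_dict() if isinstance(s, SyntheticConfig) else dict(s)
                for s in self.studies
            ],
            "master_seed": self.master_seed,
            "typicality_mode": self.typicality_mode,
            "isrsa_model": self.isrsa_model,
            "n_perm": self.n_perm,
            "toggles": {
                k: getattr(self, f"run_{k}")
                for k in ("typicality", "isrsa", "accuracy", "anchoring",
                          "valence", "confidence")
            },
            "version": __version__,
        }


@dataclass
class PipelineResult:
    effects: pd.DataFrame
    pooled: dict[str, MetaResult]
    manifest: dict
    datasets: list[StudyDataset]


def _load_studies(config: PipelineConfig) -> list[StudyDataset]:
    synth = [s for s in config.studies if isinstance(s, SyntheticConfig)]
    datasets = list(generate_multistudy(synth)) if synth else []
    for s in config.studies:
        if isinstance(s, SyntheticConfig):
            continue
        sc = StudyConfig.from_dict(s["config"]) if isinstance(s.get("config"), dict) \
            else StudyConfig.from_file(s["config"])
        datasets.append(
            read_study(s["ratings"], s["participants"], sc, study_id=s["study_id"])
        )
    return datasets


def study_effects(ds: StudyDataset, config: PipelineConfig) -> list[EffectSize]:
    """All enabled per-study effects; other-target families skip studies
    without other-target data (logged, k shrinks downstream)."""
    out: list[EffectSize] = []
    has_other = Target.OTHER.value in ds.targets_present
    targets = ["self"] + (["other"] if has_other else [])
    if not has_other:
        logger.info("study %s: no other-target data; other-target analyses skipped",
                    ds.study_id)
    for target in targets:
        if config.run_typicality:
            tr = typicality_index(ds, target, config.typicality_mode)
            out.append(typicality_effect(tr, ds.participants, ds.study_id))
        if config.run_isrsa:
            sim = similarity_matrix(ds, target)
            lz = ds.loneliness_z_by_id().loc[sim.participant_ids]
            res = ak_isrsa(
                sim, lz, model=config.isrsa_model, n_perm=config.n_perm,
                seed=(config.master_seed or 0) * 7919 + hash_stable(ds.study_id, target),
            )
            res.target = target
            out.append(res.effect(ds.study_id, f"isrsa_{target}"))
        if config.run_valence:
            out.extend(valence_effects(ds, target))
        if config.run_confidence:
            out.append(confidence_effect(ds, target))
    if has_other:
        if config.run_accuracy:
            out.append(accuracy_effect(ds))
        if config.run_anchoring:
            out.append(anchoring_effect(ds))
    return out


def hash_stable(*parts: str) -> int:
    h = hashlib.sha256("|".join(parts).encode()).hexdigest()
    return int(h[:8], 16)


def pool_effects(effects: list[EffectSize]) -> dict[str, MetaResult]:
    by_analysis: dict[str, list[EffectSize]] = {}
    for e in effects:
        by_analysis.setdefault(e.analysis, []).append(e)
    return {name: pool(group) for name, group in sorted(by_analysis.items())}


def effects_frame(effects: list[EffectSize]) -> pd.DataFrame:
    return pd.DataFrame([e.to_dict() for e in effects])[
        ["study_id", "analysis", "estimate", "variance", "n", "scale"]
    ]


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run every enabled analysis per study, pool per family, write outputs.

    Identical config + master seed reproduce byte-identical effects CSV and
    meta JSON.
    """
    config.validate()
    datasets = _load_studies(config)
    all_effects: list[EffectSize] = []
    for ds in datasets:
        logger.info("analyzing study %s (n=%d)", ds.study_id, ds.n_participants)
        all_effects.extend(study_effects(ds, config))
    effects = effects_frame(all_effects)
    pooled = pool_effects(all_effects)

    cfg = config.canonical_dict()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "version": __version__,
        "n_studies": len(datasets),
        "analyses": sorted(pooled),
    }
    result = PipelineResult(effects=effects, pooled=pooled, manifest=manifest,
                            datasets=datasets)
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        effects.to_csv(out / "effects.csv", index=False)
        with open(out / "meta.json", "w") as fh:
            json.dump({k: v.to_dict() for k, v in pooled.items()}, fh,
                      indent=2, sort_keys=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        for name, mr in pooled.items():
            forest = forest_table(all_effects, mr)
            forest.to_csv(out / f"forest_{name}.csv", index=False)
        with open(out / "report.txt", "w") as fh:
            fh.write(make_report(result))
    return result


def forest_table(effects: list[EffectSize], pooled: MetaResult) -> pd.DataFrame:
    """Per-study rows plus the pooled row, forest-plot ready."""
    rows = []
    group = [e for e in effects if e.analysis == pooled.analysis]
    w_sum = sum(1.0 / (e.variance + pooled.tau2) for e in group)
    for e in group:
        se = e.variance**0.5
        rows.append(
            dict(
                row=e.study_id, estimate=e.estimate,
                ci_lo=e.estimate - 1.96 * se, ci_hi=e.estimate + 1.96 * se,
                weight=(1.0 / (e.variance + pooled.tau2)) / w_sum,
            )
        )
    rows.append(
        dict(row="pooled", estimate=pooled.pooled,
             ci_lo=pooled.ci95[0], ci_hi=pooled.ci95[1], weight=1.0)
    )
    return pd.DataFrame(rows)


def make_report(result: PipelineResult) -> str:
    """Human-readable summary: pooled table plus a sign-pattern check."""
    lines = ["Pooled effects", "=" * 70]
    header = f"{'analysis':<22}{'k':>3}{'pooled':>10}{'se':>8}{'p':>10}{'tau2':>9}{'I2%':>7}"
    lines.append(header)
    for name, mr in result.pooled.items():
        i2 = f"{mr.i2:6.1f}" if mr.i2 is not None else "   n/a"
        lines.append(
            f"{name:<22}{mr.k:>3}{mr.pooled:>10.4f}{mr.se:>8.4f}"
            f"{mr.p:>10.4g}{mr.tau2:>9.4g}{i2:>7}"
        )
    lines += ["", "Sign pattern vs. expected directions", "-" * 50]
    for name, sign in EXPECTED_DIRECTIONS.items():
        if name not in result.pooled:
            lines.append(f"{name:<22} absent")
            continue
        got = result.pooled[name].pooled
        ok = "match" if (got > 0) == (sign > 0) else "MISMATCH"
        lines.append(f"{name:<22} expected {'+' if sign > 0 else '-'}  "
                     f"got {got:+.4f}  {ok}")
    return "\n".join(lines) + "\n"


def default_pipeline(
    master_seed: int,
    effects: bool = True,
    n_scale: float = 1.0,
    n_perm: int = 1000,
    out_dir: str | Path = "emotrans_out",
) -> PipelineConfig:
    """Seven-study synthetic pipeline mirroring the bundled designs."""
    return PipelineConfig(
        studies=list(default_suite(master_seed, effects=effects, n_scale=n_scale)),
        master_seed=master_seed,
        n_perm=n_perm,
        out_dir=out_dir,
    )
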