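"""Random-effects meta-analysis: REML tau^2, inverse-variance pooling, I^2.

Study-level estimates enter as :class:`EffectSize` records — standardized
mixed-model coefficients on the ``beta`` scale, or Fisher-z transformed
correlations (back-transformed with ``tanh`` for reporting).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .data import ValidationError

__all__ = [
    "EffectSize",
    "MetaResult",
    "fisher_z",
    "reml_tau2",
    "reml_criterion",
    "i_squared",
    "pool",
]


@dataclass(frozen=True)
class EffectSize:
    """One study-level estimate with its sampling variance."""

    study_id: str
    analysis: str
    estimate: float
    variance: float
    n: int
    scale: str  # "beta" | "fisher_z"

    def __post_init__(self) -> None:
        if self.variance <= 0 or not np.isfinite(self.variance):
            raise ValidationError(
                f"{self.analysis}/{self.study_id}: variance must be positive, "
                f"got {self.variance}"
            )
        if self.scale not in ("beta", "fisher_z"):
            raise ValidationError(f"unknown effect scale {self.scale!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MetaResult:
    analysis: str
    k: int
    pooled: float
    se: float
    ci95: tuple[float, float]
    z: float
    p: float
    tau2: float
    i2: float | None
    scale: str
    back_transformed: float | None = None
    back_transformed_ci95: tuple[float, float] | None = None
    single_study: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ci95"] = list(self.ci95)
        if self.back_transformed_ci95 is not None:
            d["back_transformed_ci95"] = list(self.back_transformed_ci95)
        return d


def fisher_z(r: float, n: int) -> tuple[float, float]:
    """Fisher transform with variance 1/(n-3); rejects |r| = 1."""
    if not (-1.0 < r < 1.0):
        raise ValidationError(f"degenerate perfect correlation r={r}")
    if n < 4:
        raise ValidationError(f"need n >= 4 for a Fisher-z variance, got n={n}")
    return float(np.arctanh(r)), 1.0 / (n - 3)


def reml_criterion(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Restricted log-likelihood of the random-effects model at tau2."""
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    return float(
        -0.5 * np.sum(np.log(v + tau2))
        - 0.5 * np.log(np.sum(w))
        - 0.5 * np.sum(w * (y - mu) ** 2)
    )


def reml_tau2(
    effects: list[EffectSize] | tuple[np.ndarray, np.ndarray],
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> float:
    """Between-study variance by REML (Fisher-scoring fixed point).

    Iterates ``tau2 <- sum(w^2 ((y-mu)^2 - v)) / sum(w^2) + 1/sum(w)`` with
    ``w = 1/(v + tau2)``, truncated at zero, to the stated tolerance.
    """
    if isinstance(effects, tuple):
        y, v = map(np.asarray, effects)
    else:
        y = np.array([e.estimate for e in effects], dtype=float)
        v = np.array([e.variance for e in effects], dtype=float)
    if (v <= 0).any():
        raise ValidationError("all sampling variances must be positive")
    k = len(y)
    if k < 2:
        return 0.0
    tau2 = max(float(np.var(y, ddof=1) - np.mean(v)), 0.0)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        new = np.sum(w**2 * ((y - mu) ** 2 - v)) / np.sum(w**2) + 1.0 / np.sum(w)
        new = max(float(new), 0.0)
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    # Fall back to direct maximization of the restricted likelihood.
    from scipy import optimize

    res = optimize.minimize_scalar(
        lambda t: -reml_criterion(t, y, v),
        bounds=(0.0, max(10.0 * float(np.var(y, ddof=1)), 1.0)),
        method="bounded",
        options=dict(xatol=1e-12),
    )
    if not res.success:
        raise RuntimeError("REML tau2 estimation failed to converge")
    return max(float(res.x), 0.0)


def i_squared(tau2: float, variances: list[float] | np.ndarray) -> float | None:
    """Heterogeneity percentage against the typical within-study variance.

    ``I2 = 100 tau2 / (tau2 + s2)`` with
    ``s2 = (k-1) sum(w) / ((sum w)^2 - sum(w^2))`` and ``w = 1/v``.
    """
    v = np.asarray(variances, dtype=float)
    if (v <= 0).any():
        raise ValidationError("variances must be positive")
    k = len(v)
    if k < 2:
        return None
    w = 1.0 / v
    s2 = (k - 1) * np.sum(w) / (np.sum(w) ** 2 - np.sum(w**2))
    return float(100.0 * tau2 / (tau2 + s2))


def pool(effects: list[EffectSize], tau2: float | None = None) -> MetaResult:
    """Inverse-variance random-effects pooling with Wald-normal inference.

    ``tau2`` defaults to the REML estimate; passing a value fixes it (e.g.
    for a DerSimonian-Laird cross-check).
    """
    if not effects:
        raise ValidationError("no effects to pool")
    labels = {e.analysis for e in effects}
    scales = {e.scale for e in effects}
    if len(labels) > 1:
        raise ValidationError(f"mixed analysis labels: {sorted(labels)}")
    if len(scales) > 1:
        raise ValidationError(f"mixed effect scales: {sorted(scales)}")
    scale = effects[0].scale
    y = np.array([e.estimate for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    k = len(effects)
    single = k == 1
    if tau2 is None:
        tau2 = 0.0 if single else reml_tau2(effects)
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    ci = (pooled - 1.96 * se, pooled + 1.96 * se)
    i2 = i_squared(tau2, v) if not single else None
    back = back_ci = None
    if scale == "fisher_z":
        back = float(np.tanh(pooled))
        back_ci = (float(np.tanh(ci[0])), float(np.tanh(ci[1])))
    return MetaResult(
        analysis=effects[0].analysis,
        k=k,
        pooled=pooled,
        se=se,
        ci95=ci,
        z=float(z),
        p=p,
        tau2=float(tau2),
        i2=i2,
        scale=scale,
        back_transformed=back,
        back_transformed_ci95=back_ci,
        single_study=single,
    )
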