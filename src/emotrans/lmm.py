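"""Gaussian linear mixed models with crossed random intercepts, fit by REML.

The model is ``y = X b + sum_k Z_k u_k + e`` with ``u_k ~ N(0, s2_k I)``
and ``e ~ N(0, s2_e I)``.  Writing ``theta_k = s2_k / s2_e`` and
``H = I + Z G Z'`` (``G`` diagonal in the theta's), both ``b`` and ``s2_e``
profile out of the restricted likelihood, leaving an optimization over at
most a handful of log-thetas.  All linear algebra runs through the q x q
inner matrix ``I + G^1/2 Z'Z G^1/2`` (Woodbury / Sylvester), where q is the
total number of random levels — participants plus two emotion factors —
so a fit on tens of thousands of rows takes well under a second.

Design matrices are built from term strings: continuous columns by name,
categoricals as ``C(col)`` (reference-coded), and pairwise interactions
with ``:``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .data import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["LMMSpec", "LMMFit", "SimpleSlope", "fit_lmm", "wald_table", "simple_slopes"]

_BOUNDARY_THETA = 1e-8


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LMMSpec:
    outcome: str
    fixed_terms: list[str]
    random_intercept_factors: list[str] = field(default_factory=list)
    standardize_continuous: bool = False
    references: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.fixed_terms:
            for piece in t.split(":"):
                name = piece[2:-1] if piece.startswith("C(") else piece
                if name == self.outcome:
                    raise ValidationError(f"outcome {self.outcome!r} used as predictor")


@dataclass
class LMMFit:
    beta: np.ndarray
    beta_names: list[str]
    vcov_beta: np.ndarray
    variance_components: dict[str, float]
    boundary: dict[str, bool]
    reml_loglik: float
    converged: bool
    n_obs: int
    n_levels: dict[str, int]
    spec: LMMSpec
    references: dict[str, str] = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.beta[self.beta_names.index(name)])

    def se(self, name: str) -> float:
        i = self.beta_names.index(name)
        return float(np.sqrt(self.vcov_beta[i, i]))


@dataclass
class SimpleSlope:
    category: str
    slope: float
    se: float
    ci95: tuple[float, float]
    p: float


def _term_columns(
    table: pd.DataFrame, term: str, references: dict[str, str]
) -> tuple[np.ndarray, list[str]]:
    """Columns and names for one term; interactions multiply elementwise."""
    blocks: list[tuple[np.ndarray, list[str]]] = []
    for piece in term.split(":"):
        if piece.startswith("C(") and piece.endswith(")"):
            col = piece[2:-1]
            if col not in table.columns:
                raise ValidationError(f"column {col!r} not in table")
            levels = sorted(map(str, table[col].unique()))
            ref = references.setdefault(col, levels[0])
            if ref not in levels:
                raise ValidationError(f"reference level {ref!r} not among {levels}")
            others = [l for l in levels if l != ref]
            vals = table[col].astype(str).to_numpy()
            mat = np.column_stack([(vals == l).astype(float) for l in others])
            blocks.append((mat, [f"C({col})[{l}]" for l in others]))
        else:
            if piece not in table.columns:
                raise ValidationError(f"column {piece!r} not in table")
            blocks.append((table[piece].to_numpy(float)[:, None], [piece]))
    mat, names = blocks[0]
    for bmat, bnames in blocks[1:]:
        mat = np.einsum("ij,ik->ijk", mat, bmat).reshape(len(mat), -1)
        names = [f"{a}:{b}" for a in names for b in bnames]
    return mat, names


def build_design(
    table: pd.DataFrame, fixed_terms: list[str], references: dict[str, str] | None = None
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Fixed-effect design matrix with an intercept, reference coding.

    Returns the matrix, column names, and the resolved reference level per
    categorical (defaults are filled in from the sorted data levels).
    """
    references = dict(references or {})
    cols = [np.ones((len(table), 1))]
    names = ["Intercept"]
    for term in fixed_terms:
        mat, tnames = _term_columns(table, term, references)
        cols.append(mat)
        names.extend(tnames)
    X = np.hstack(cols)
    return X, names, references


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    if (diag < tol).any():
        bad = [names[i] for i in np.where(diag < tol)[0]]
        raise ValidationError(f"design matrix rank-deficient; aliased columns: {bad}")


class _REMLProblem:
    """Precomputed cross-products; evaluates -2 restricted log-likelihood."""

    def __init__(self, y: np.ndarray, X: np.ndarray, factors: list[np.ndarray]):
        self.n, self.p = X.shape
        self.y = y
        self.X = X
        self.K = len(factors)
        self.block_sizes = [int(f.max()) + 1 for f in factors]
        self.q = sum(self.block_sizes)
        if self.K:
            cols = []
            offset = 0
            row_idx = np.arange(self.n)
            data, rows, colind = [], [], []
            for f, b in zip(factors, self.block_sizes):
                rows.append(row_idx)
                colind.append(f + offset)
                data.append(np.ones(self.n))
                offset += b
            Z = sp.csr_matrix(
                (np.concatenate(data), (np.concatenate(rows), np.concatenate(colind))),
                shape=(self.n, self.q),
            )
            self.ZtZ = np.asarray(Z.T.dot(Z).todense())
            self.XtZ = X.T @ Z.toarray() if self.q < 4000 else np.asarray((Z.T @ X).T)
            self.ytZ = np.asarray(Z.T.dot(y)).ravel()
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self._eye_q = np.eye(self.q) if self.K else None

    def _sqrt_g(self, theta: np.ndarray) -> np.ndarray:
        return np.sqrt(np.repeat(theta, self.block_sizes))

    def profile(self, theta: np.ndarray) -> dict:
        """GLS quantities at fixed variance ratios theta."""
        n, p = self.n, self.p
        if self.K == 0 or np.all(theta == 0):
            XtHiX, XtHiy, yHiy, logdetH = self.XtX, self.Xty, self.yty, 0.0
        else:
            g = self._sqrt_g(theta)
            M = self._eye_q + (g[:, None] * self.ZtZ) * g[None, :]
            L = np.linalg.cholesky(M)
            logdetH = 2.0 * float(np.log(np.diag(L)).sum())
            # H^-1 A = A - Zg M^-1 (Zg)' A  via precomputed cross-products
            ZgtX = (self.XtZ * g[None, :]).T        # q x p
            Zgty = self.ytZ * g                     # q
            sx = solve_triangular(L, ZgtX, lower=True, check_finite=False)
            sy = solve_triangular(L, Zgty, lower=True, check_finite=False)
            XtHiX = self.XtX - sx.T @ sx
            XtHiy = self.Xty - sx.T @ sy
            yHiy = self.yty - float(sy @ sy)
        cf = np.linalg.cholesky(XtHiX)
        beta = cho_solve((cf, True), XtHiy, check_finite=False)
        rss = max(yHiy - float(beta @ XtHiy), 1e-300)
        sigma2_e = rss / (n - p)
        logdet_XtHiX = 2.0 * float(np.log(np.diag(cf)).sum())
        neg2 = (
            (n - p) * (np.log(2.0 * np.pi * sigma2_e) + 1.0) + logdetH + logdet_XtHiX
        )
        return dict(
            beta=beta, sigma2_e=sigma2_e, neg2=neg2,
            XtHiX=XtHiX, rss=rss,
        )

    def neg2reml(self, log_theta: np.ndarray) -> float:
        return self.profile(np.exp(log_theta))["neg2"]


def fit_lmm(table: pd.DataFrame, spec: LMMSpec) -> LMMFit:
    """REML fit; variance ratios optimized on the log scale.

    Variance components pinned to the zero boundary are reported as exactly
    0 with a boundary flag.  Raises on rank-deficient designs; a fit that
    fails to converge is returned with ``converged=False``.
    """
    table = table.reset_index(drop=True)
    work = table.copy()
    if spec.standardize_continuous:
        from .data import standardize

        cont = {spec.outcome}
        for t in spec.fixed_terms:
            for piece in t.split(":"):
                if not piece.startswith("C("):
                    cont.add(piece)
        for col in cont:
            work[col] = standardize(work[col].to_numpy(float))

    y = work[spec.outcome].to_numpy(float)
    X, names, resolved_refs = build_design(work, spec.fixed_terms, spec.references)
    _check_rank(X, names)

    factors = []
    n_levels = {}
    for col in spec.random_intercept_factors:
        codes, uniques = pd.factorize(work[col], sort=True)
        factors.append(codes.astype(np.int64))
        n_levels[col] = len(uniques)

    prob = _REMLProblem(y, X, factors)
    K = prob.K
    converged = True
    try:
        if K == 0:
            res = prob.profile(np.array([]))
            theta = np.array([])
        else:
            x0 = np.full(K, np.log(0.1))
            opt = optimize.minimize(
                prob.neg2reml, x0, method="L-BFGS-B",
                bounds=[(-30.0, 10.0)] * K,
                options=dict(ftol=1e-14, gtol=1e-10, maxiter=500),
            )
            # Polish: Nelder-Mead nails the optimum to the precision the
            # closed-form equivalence contracts require; budget kept modest.
            polish = optimize.minimize(
                prob.neg2reml, opt.x, method="Nelder-Mead",
                options=dict(xatol=1e-9, fatol=1e-11, maxiter=150 * K, maxfev=150 * K),
            )
            best = polish if polish.fun <= opt.fun else opt
            converged = bool(opt.success or polish.success)
            theta = np.exp(best.x)
            theta[theta < _BOUNDARY_THETA] = 0.0
            res = prob.profile(theta)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            f"degenerate model (singular system during REML): {exc}"
        ) from exc

    sigma2_e = res["sigma2_e"]
    vcov = sigma2_e * np.linalg.inv(res["XtHiX"])
    vcov = 0.5 * (vcov + vcov.T)
    var_comp = {"residual": float(sigma2_e)}
    boundary = {}
    for col, th in zip(spec.random_intercept_factors, theta):
        var_comp[col] = float(th * sigma2_e)
        boundary[col] = bool(th == 0.0)
    fit = LMMFit(
        beta=res["beta"],
        beta_names=names,
        vcov_beta=vcov,
        variance_components=var_comp,
        boundary=boundary,
        reml_loglik=-0.5 * float(res["neg2"]),
        converged=converged,
        n_obs=prob.n,
        n_levels=n_levels,
        spec=spec,
        references=resolved_refs,
    )
    if sigma2_e < 1e-10 * max(np.var(y), 1e-30) or not np.isfinite(fit.reml_loglik):
        raise ValidationError(
            "degenerate fit: residual variance is (numerically) zero"
        )
    if not converged:
        logger.warning("REML optimizer did not report convergence")
    return fit


def wald_table(fit: LMMFit) -> pd.DataFrame:
    """Per-coefficient estimate, SE, z, two-sided normal p, and 95% CI."""
    if not fit.converged:
        raise ConvergenceError("refusing inference on a non-converged fit")
    se = np.sqrt(np.diag(fit.vcov_beta))
    z = np.divide(fit.beta, se, out=np.zeros_like(fit.beta), where=se > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "term": fit.beta_names,
            "estimate": fit.beta,
            "se": se,
            "z": z,
            "p": p,
            "ci_lo": fit.beta - 1.96 * se,
            "ci_hi": fit.beta + 1.96 * se,
        }
    )


def simple_slopes(fit: LMMFit, continuous: str, categorical: str) -> list[SimpleSlope]:
    """Per-category slope of the continuous predictor from an interaction fit.

    slope(c) = b_cont + b_{cont:c} (zero for the reference category), with
    the SE from the corresponding linear combination of ``vcov_beta``.
    """
    names = fit.beta_names
    if continuous not in names:
        raise ValidationError(f"term {continuous!r} absent from fit")
    i_main = names.index(continuous)
    prefix_a = f"{continuous}:C({categorical})["
    prefix_b = f"C({categorical})["
    inter: dict[str, int] = {}
    for j, nm in enumerate(names):
        if nm.startswith(prefix_a) and nm.endswith("]"):
            inter[nm[len(prefix_a):-1]] = j
        elif ":" in nm:
            left, right = nm.split(":", 1)
            if left.startswith(prefix_b) and left.endswith("]") and right == continuous:
                inter[left[len(prefix_b):-1]] = j
    if not inter:
        raise ValidationError(
            f"no {continuous} x {categorical} interaction terms in fit"
        )
    ref = fit.references.get(categorical)
    if ref is None:
        raise ValidationError(f"no reference level recorded for {categorical!r}")
    out = []
    v = fit.vcov_beta
    for cat in sorted(set(inter) | {ref}):
        if cat == ref:
            slope = float(fit.beta[i_main])
            se = float(np.sqrt(v[i_main, i_main]))
        else:
            j = inter[cat]
            slope = float(fit.beta[i_main] + fit.beta[j])
            se = float(np.sqrt(v[i_main, i_main] + v[j, j] + 2.0 * v[i_main, j]))
        if se <= 0:
            raise ValidationError(f"non-positive SE for simple slope of {cat}")
        z = slope / se
        out.append(
            SimpleSlope(
                category=cat,
                slope=slope,
                se=se,
                ci95=(slope - 1.96 * se, slope + 1.96 * se),
                p=float(2.0 * stats.norm.sf(abs(z))),
            )
        )
    return out
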