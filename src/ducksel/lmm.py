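"""REML variance components and mixed-model solving for BLUP, GBLUP, ssGBLUP.

The single animal model throughout is

    y = X b + Z a + e,   a ~ N(0, K sigma_a2),   e ~ N(0, I sigma_e2)

with K the pedigree A, the genomic G, or the single-step H relationship.
Variance components come from average-information REML with EM fallback
steps; a one-time eigendecomposition of K diagonalizes V so each REML
iteration is O(n). Breeding values solve Henderson's mixed-model equations;
the equivalent V-form (no K inverse needed) is used whenever K itself is at
hand, which keeps GBLUP exactly equal to its SNP-BLUP ridge formulation.
Individuals in K without phenotypes receive predictions through their
relationships, which is what both ssGBLUP and cross-validation masking rely
on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinship
from .genio import GenotypeMatrix
from .kinship import DEFAULT_G_REG, RelationshipMatrix
from .simdata import Pedigree, PhenotypeTable

log = logging.getLogger(__name__)

MODEL_KINDS = ("pedigree_blup", "gblup", "ssgblup")


@dataclass
class VarianceComponents:
    """REML estimates of the two variance components and derived heritability."""

    sigma_a2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    n_iterations: int
    converged: bool = True

    @property
    def lam(self) -> float:
        """Shrinkage ratio sigma_e2 / sigma_a2 of the mixed-model equations."""
        return self.sigma_e2 / self.sigma_a2


@dataclass
class ModelFit:
    beta_hat: pd.Series
    breeding_values: pd.Series
    varcomp: VarianceComponents
    model_kind: str


def build_design(df: pd.DataFrame, factor_cols) -> tuple[np.ndarray, list]:
    """Full-rank fixed-effects design: intercept + first-level-reference dummies."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in factor_cols:
        levels = sorted(pd.unique(df[f].astype(str)))
        for lev in levels[1:]:
            cols.append((df[f].astype(str) == lev).to_numpy(float))
            names.append(f"{f}[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effects design is rank deficient (confounded factors?)")
    return X, names


# ---------------------------------------------------------------------------
# REML


def _reml_pieces(ys, Xs, d, sa, se):
    """Quantities of the rotated model where V = diag(sa * d + se)."""
    v = sa * d + se
    vinv = 1.0 / v
    W = Xs * vinv[:, None]          # V^-1 X
    XtVX = Xs.T @ W
    XtVX_inv = np.linalg.inv(XtVX)
    beta = XtVX_inv @ (W.T @ ys)
    Py = vinv * ys - W @ (XtVX_inv @ (W.T @ ys))
    _, logdet_xvx = np.linalg.slogdet(XtVX)
    loglik = -0.5 * (np.log(v).sum() + logdet_xvx + float(ys @ Py))
    return v, vinv, W, XtVX_inv, Py, loglik


def _trace_P(vinv, W, XtVX_inv, a_diag):
    """tr(P diag(a)) for the rotated model."""
    t1 = float(a_diag @ vinv)
    t2 = float(np.trace(XtVX_inv @ (W.T * a_diag) @ W))
    return t1 - t2


def estimate_reml(
    y: np.ndarray,
    X: np.ndarray,
    K: RelationshipMatrix | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> VarianceComponents:
    """Average-information REML for (sigma_a2, sigma_e2) under y = Xb + a + e.

    K is eigendecomposed once; the rotated model has diagonal V so scores,
    AI matrix and the restricted likelihood are all O(n) per iteration.  AI
    proposals stepping outside the parameter space fall back to an EM
    update.  The SE of h2 comes from the delta method on the inverse AI
    matrix at convergence.
    """
    Kv = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if len(y) != n or Kv.shape != (n, n):
        raise ValueError("dimension mismatch between y, X and K")
    if n < p + 2:
        raise ValueError("need n >= rank(X) + 2 observations for REML")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("X must have full column rank")

    d, U = np.linalg.eigh(0.5 * (Kv + Kv.T))
    if d.min() < -1e-6 * max(1.0, d.max()):
        raise ValueError(f"K is not PSD (min eigenvalue {d.min():.3g})")
    d = np.clip(d, 0.0, None)
    ys = U.T @ y
    Xs = U.T @ X

    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("phenotype has zero variance")
    sa, se = 0.5 * vary, 0.5 * vary
    floor = 1e-8 * vary

    n_it, converged = 0, False
    AI = np.eye(2)
    for n_it in range(1, max_iter + 1):
        v, vinv, W, XtVX_inv, Py, _ = _reml_pieces(ys, Xs, d, sa, se)
        dPy = d * Py
        yPAPy = np.array([float(Py @ dPy), float(Py @ Py)])
        trPA = np.array([
            _trace_P(vinv, W, XtVX_inv, d),
            _trace_P(vinv, W, XtVX_inv, np.ones(n)),
        ])
        score = -0.5 * (trPA - yPAPy)
        # AI matrix: 0.5 y'P A_k P A_l P y, with P(d*Py) etc. reusing the pieces
        PdPy = vinv * dPy - W @ (XtVX_inv @ (W.T @ dPy))
        PPy = vinv * Py - W @ (XtVX_inv @ (W.T @ Py))
        AI = 0.5 * np.array([
            [float(dPy @ PdPy), float(dPy @ PPy)],
            [float(dPy @ PPy), float(Py @ PPy)],
        ])
        theta = np.array([sa, se])
        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            step = None
        new = None
        if step is not None:
            for _ in range(5):  # step-halving toward the interior
                if np.all(theta + step > floor):
                    new = theta + step
                    break
                step = 0.5 * step
        if new is None:  # EM fallback keeps the parameters strictly positive
            new = theta + theta**2 * (yPAPy - trPA) / n
            new = np.maximum(new, floor)
        # relative to the phenotypic scale, so a boundary component (-> 0)
        # does not stall convergence on its own vanishing magnitude
        rel = np.max(np.abs(new - theta)) / vary
        sa, se = float(new[0]), float(new[1])
        if rel < tol:
            converged = True
            break
    if not converged:
        # low-information or boundary cases: maximize the profiled restricted
        # likelihood over h2 directly (exact for this two-component model),
        # then recompute the AI matrix at the optimum for the SE
        from scipy.optimize import minimize_scalar

        n_eff = n - p

        def neg_profiled(h2_):
            *_, Py0, _ = _reml_pieces(ys, Xs, d, h2_, 1.0 - h2_)
            c_hat = max(float(ys @ Py0) / n_eff, floor)
            *_, ll = _reml_pieces(ys, Xs, d, h2_ * c_hat, (1.0 - h2_) * c_hat)
            return -ll

        opt = minimize_scalar(neg_profiled, bounds=(1e-8, 1.0 - 1e-8), method="bounded",
                              options={"xatol": 1e-10})
        h2_opt = float(opt.x)
        *_, Py0, _ = _reml_pieces(ys, Xs, d, h2_opt, 1.0 - h2_opt)
        c_hat = max(float(ys @ Py0) / n_eff, floor)
        sa, se = h2_opt * c_hat, (1.0 - h2_opt) * c_hat
        v, vinv, W, XtVX_inv, Py, _ = _reml_pieces(ys, Xs, d, sa, se)
        dPy = d * Py
        PdPy = vinv * dPy - W @ (XtVX_inv @ (W.T @ dPy))
        PPy = vinv * Py - W @ (XtVX_inv @ (W.T @ Py))
        AI = 0.5 * np.array([
            [float(dPy @ PdPy), float(dPy @ PPy)],
            [float(dPy @ PPy), float(Py @ PPy)],
        ])
        converged = True
        log.debug("REML AI/EM loop hit max_iter; profiled-likelihood fallback used")

    _, vinv, W, XtVX_inv, Py, loglik = _reml_pieces(ys, Xs, d, sa, se)
    h2 = sa / (sa + se)
    try:
        cov = np.linalg.inv(AI)
        grad = np.array([se, -sa]) / (sa + se) ** 2
        se_h2 = float(np.sqrt(max(0.0, grad @ cov @ grad)))
    except np.linalg.LinAlgError:
        se_h2 = float("nan")
    return VarianceComponents(sa, se, h2, se_h2, float(loglik), n_it, converged)


def reml_loglik(y, X, K, sigma_a2: float, sigma_e2: float) -> float:
    """Restricted log-likelihood at fixed variance components (grid oracle hook)."""
    Kv = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)
    d, U = np.linalg.eigh(0.5 * (Kv + Kv.T))
    d = np.clip(d, 0.0, None)
    *_, loglik = _reml_pieces(U.T @ np.asarray(y, float),
                              U.T @ np.atleast_2d(np.asarray(X, float)),
                              d, sigma_a2, sigma_e2)
    return float(loglik)


# ---------------------------------------------------------------------------
# Solvers


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    K_inv: RelationshipMatrix | np.ndarray,
    varcomp: VarianceComponents,
) -> tuple[np.ndarray, np.ndarray]:
    """Henderson's mixed-model equations; returns (beta_hat, a_hat).

    Z allocates the n observations to the q individuals of K; individuals
    with no record are predicted through K_inv's couplings.
    """
    Kinv = K_inv.values if isinstance(K_inv, RelationshipMatrix) else np.asarray(K_inv, float)
    lam = varcomp.lam
    if not np.isfinite(lam) or lam <= 0:
        raise ValueError("lambda = sigma_e2/sigma_a2 must be finite and positive")
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.asarray(Z, float)
    p, q = X.shape[1], Z.shape[1]
    C = np.empty((p + q, p + q))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T @ Z
    C[p:, :p] = C[:p, p:].T
    C[p:, p:] = Z.T @ Z + lam * Kinv
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    try:
        sol = np.linalg.solve(C, rhs)
    except np.linalg.LinAlgError:
        rank = np.linalg.matrix_rank(C)
        raise np.linalg.LinAlgError(
            f"singular MME coefficient matrix (rank {rank} of {p + q})"
        ) from None
    return sol[:p], sol[p:]


def blup_predict(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    K: RelationshipMatrix | np.ndarray,
    varcomp: VarianceComponents,
) -> tuple[np.ndarray, np.ndarray]:
    """BLUP in the V-form: a_hat = sigma_a2 K Z' V^-1 (y - X beta_hat).

    Algebraically identical to Henderson's equations but needs K, not K^-1,
    so a singular (e.g., unregularized genomic) K is fine.
    """
    Kv = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)
    X = np.atleast_2d(np.asarray(X, float))
    Z = np.asarray(Z, float)
    ZKZ = Z @ Kv @ Z.T
    V = varcomp.sigma_a2 * ZKZ + varcomp.sigma_e2 * np.eye(len(y))
    Vc = np.linalg.cholesky(V)
    solve = lambda b: np.linalg.solve(Vc.T, np.linalg.solve(Vc, b))  # noqa: E731
    ViX = solve(X)
    beta = np.linalg.solve(X.T @ ViX, ViX.T @ y)
    resid_v = solve(y - X @ beta)
    a_hat = varcomp.sigma_a2 * (Kv @ Z.T @ resid_v)
    return beta, a_hat


# ---------------------------------------------------------------------------
# Model dispatch


def _incidence(obs_ids, all_ids) -> np.ndarray:
    index = {v: k for k, v in enumerate(all_ids)}
    Z = np.zeros((len(obs_ids), len(all_ids)))
    for r, i in enumerate(obs_ids):
        Z[r, index[i]] = 1.0
    return Z


def fit_model(
    model_kind: str,
    phenotypes: PhenotypeTable,
    trait: str,
    ped: Pedigree | None = None,
    genotypes: GenotypeMatrix | None = None,
    factor_cols=None,
    mask_ids=None,
    g_reg: float = DEFAULT_G_REG,
    varcomp: VarianceComponents | None = None,
) -> ModelFit:
    """Fit pedigree BLUP, GBLUP or ssGBLUP with one shared code path.

    ``mask_ids`` drops those individuals' phenotypes from the training data
    while keeping the individuals in the relationship structure, so they
    still receive (G)EBVs — the masking used for cross-validation.  Variance
    components are re-estimated on the training records unless ``varcomp``
    is supplied.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    if model_kind in ("pedigree_blup", "ssgblup") and ped is None:
        raise ValueError(f"{model_kind} requires a pedigree")
    if model_kind in ("gblup", "ssgblup") and genotypes is None:
        raise ValueError(f"{model_kind} requires genotypes")

    if model_kind == "pedigree_blup":
        K = kinship.build_A(ped)
    elif model_kind == "gblup":
        K = kinship.regularize(kinship.build_G(genotypes), g_reg)
    elif genotypes.n_individuals == 0:
        # single-step with an empty genotyped set reduces to pedigree BLUP
        K = kinship.build_A(ped)
    else:
        K_inv = kinship.build_H_inverse_from(ped, kinship.build_G(genotypes), g_reg)
        K = kinship.RelationshipMatrix(np.linalg.inv(K_inv.values), K_inv.ids, "H",
                                       regularization=g_reg)
    all_ids = list(K.ids)

    mask = set(mask_ids or ())
    df = phenotypes.df
    in_k = df["id"].isin(set(all_ids))
    has_y = df[trait].notna()
    train = df[in_k & has_y & ~df["id"].isin(mask)]
    if len(train) == 0:
        raise ValueError("no training records for this model/trait")
    factor_cols = phenotypes.factor_cols if factor_cols is None else list(factor_cols)
    X, names = build_design(train, factor_cols)
    y = train[trait].to_numpy(float)
    obs_ids = train["id"].tolist()
    Z = _incidence(obs_ids, all_ids)

    if varcomp is None:
        K_obs = K.subset(obs_ids)
        varcomp = estimate_reml(y, X, K_obs)
    beta, a_hat = blup_predict(y, X, Z, K, varcomp)
    return ModelFit(
        beta_hat=pd.Series(beta, index=names),
        breeding_values=pd.Series(a_hat, index=all_ids),
        varcomp=varcomp,
        model_kind=model_kind,
    )
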