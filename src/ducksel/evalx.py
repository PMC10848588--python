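"""Evaluation machinery: fivefold CV, reliability, model comparison, marker density.

Prediction reliability for a model x trait is the mean over cross-validation
folds of the squared Pearson correlation between the (G)EBVs of validation
individuals — whose phenotypes were masked during training — and their
adjusted phenotypes (phenotype minus fitted fixed effects).  The marker
density experiment subsamples the panel at a grid of densities, rebuilds G
and repeats the CV many times; "predictive capability" at a density is its
mean reliability divided by the mean reliability at the largest density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import genio, kinship, lmm
from .bayes import BayesModelSpec, MCMCConfig, gebv_from_effects, run_sampler
from .genio import GenotypeMatrix
from .simdata import Pedigree, PhenotypeTable

log = logging.getLogger(__name__)


@dataclass
class CVScheme:
    """Partition of ids into k folds of near-equal size (differ by <= 1)."""

    fold_assignment: dict
    k: int
    seed: int

    def fold_ids(self, fold: int) -> list:
        return [i for i, f in self.fold_assignment.items() if f == fold]


def make_folds(ids, k: int = 5, seed: int = 0) -> CVScheme:
    """Seeded uniform partition into k folds; larger folds come first.

    941 ids at k=5 give fold sizes (189, 188, 188, 188, 188), i.e. the
    753-or-752 / 188-or-189 train/validation division.
    """
    ids = list(ids)
    if k > len(ids):
        raise ValueError(f"cannot make {k} folds from {len(ids)} ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {}
    for fold, chunk in enumerate(np.array_split(order, k), start=1):
        for idx in chunk:
            assignment[ids[idx]] = fold
    return CVScheme(assignment, k, seed)


@dataclass
class ReliabilityResult:
    """Per-fold and mean squared Pearson correlations for one model x trait."""

    per_fold_r2: list
    model_kind: str
    trait: str

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.per_fold_r2))


def adjusted_phenotype(
    phenotypes: PhenotypeTable,
    trait: str,
    factor_cols=None,
    K: kinship.RelationshipMatrix | None = None,
) -> pd.Series:
    """y* = y - X beta_hat, the validation target of the reliability statistic.

    beta_hat comes from a full-data fit: generalized least squares jointly
    with a polygenic term when a relationship matrix is supplied (avoids
    fixed-effect bias from genetic structure), plain OLS otherwise.  The
    intercept is removed too, so with no factors y* is just centered y.
    """
    df = phenotypes.df[phenotypes.df[trait].notna()]
    factor_cols = phenotypes.factor_cols if factor_cols is None else list(factor_cols)
    for f in factor_cols:
        if df[f].isna().any():
            raise ValueError(f"missing level of factor {f!r} for some phenotyped ids")
    X, _ = lmm.build_design(df, factor_cols)
    y = df[trait].to_numpy(float)
    if K is not None:
        ids = df["id"].tolist()
        missing = [i for i in ids if i not in K._index]
        if missing:
            raise ValueError(f"phenotyped ids missing from relationship matrix: {missing[:5]}")
        vc = lmm.estimate_reml(y, X, K.subset(ids))
        beta, _ = lmm.blup_predict(y, X, np.eye(len(y)), K.subset(ids), vc)
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ beta, index=df["id"].to_numpy(object))


def reliability(
    predictions: pd.Series,
    adjusted: pd.Series,
    scheme: CVScheme,
    model_kind: str = "",
    trait: str = "",
) -> ReliabilityResult:
    """Per-fold squared Pearson correlation of predictions vs adjusted phenotypes."""
    per_fold = []
    for fold in range(1, scheme.k + 1):
        ids = [i for i in scheme.fold_ids(fold) if i in predictions.index and i in adjusted.index]
        p = predictions.loc[ids].to_numpy(float)
        a = adjusted.loc[ids].to_numpy(float)
        if len(ids) < 2 or np.std(p) == 0 or np.std(a) == 0:
            log.warning("fold %d: zero-variance predictions or targets; r2 set to 0", fold)
            per_fold.append(0.0)
            continue
        r = float(np.corrcoef(p, a)[0, 1])
        per_fold.append(r * r)
    return ReliabilityResult(per_fold, model_kind, trait)


def compare_models(table_a: pd.Series, table_b: pd.Series) -> dict:
    """Two-sided paired t-test of per-trait reliabilities of two models.

    Returns the t statistic, p-value and mean difference (a - b). A constant
    non-zero shift has zero difference variance; that degenerate case is
    reported as p -> 0 with a logged note.
    """
    traits = [t for t in table_a.index if t in table_b.index]
    if len(traits) < 2:
        raise ValueError("need at least two shared traits for a paired test")
    d = table_a.loc[traits].to_numpy(float) - table_b.loc[traits].to_numpy(float)
    mean_diff = float(d.mean())
    if np.allclose(d, d[0]):
        if d[0] == 0.0:
            return {"t": 0.0, "p": 1.0, "mean_diff": 0.0, "n_traits": len(traits)}
        log.info("paired comparison degenerate: constant non-zero difference; p -> 0")
        return {"t": float(np.inf) * np.sign(d[0]), "p": 0.0,
                "mean_diff": mean_diff, "n_traits": len(traits)}
    t, p = stats.ttest_rel(table_a.loc[traits], table_b.loc[traits])
    return {"t": float(t), "p": float(p), "mean_diff": mean_diff, "n_traits": len(traits)}


# ---------------------------------------------------------------------------
# Cross-validation drivers


def cross_validate(
    model_kind: str,
    phenotypes: PhenotypeTable,
    trait: str,
    scheme: CVScheme,
    ped: Pedigree | None = None,
    genotypes: GenotypeMatrix | None = None,
    adjusted: pd.Series | None = None,
    g_reg: float = kinship.DEFAULT_G_REG,
) -> ReliabilityResult:
    """Fivefold CV of a BLUP-family model by phenotype masking.

    Validation individuals stay in the relationship structure with their
    phenotypes masked, so every genotyped validation animal receives a
    (G)EBV from each model; variance components are re-estimated on each
    training fold.
    """
    if adjusted is None:
        adjusted = adjusted_phenotype(phenotypes, trait)
    preds = {}
    for fold in range(1, scheme.k + 1):
        mask = scheme.fold_ids(fold)
        fit = lmm.fit_model(model_kind, phenotypes, trait, ped=ped,
                            genotypes=genotypes, mask_ids=mask, g_reg=g_reg)
        for i in mask:
            if i in fit.breeding_values.index:
                preds[i] = fit.breeding_values.loc[i]
    return reliability(pd.Series(preds), adjusted, scheme, model_kind, trait)


def cross_validate_bayes(
    phenotypes: PhenotypeTable,
    trait: str,
    scheme: CVScheme,
    genotypes: GenotypeMatrix,
    model: BayesModelSpec,
    mcmc: MCMCConfig | None = None,
    adjusted: pd.Series | None = None,
) -> ReliabilityResult:
    """Fivefold CV of a Bayesian-alphabet model.

    Each fold's sampler trains on the other four folds; validation GEBVs are
    computed from the posterior-mean effects with training-set centering.
    """
    if adjusted is None:
        adjusted = adjusted_phenotype(phenotypes, trait)
    mcmc = mcmc or MCMCConfig()
    preds = {}
    for fold in range(1, scheme.k + 1):
        val_ids = [i for i in scheme.fold_ids(fold) if i in set(genotypes.individual_ids)]
        train_tbl = PhenotypeTable(
            phenotypes.df[~phenotypes.df["id"].isin(val_ids)].reset_index(drop=True),
            trait_cols=phenotypes.trait_cols, factor_cols=phenotypes.factor_cols,
        )
        fold_mcmc = MCMCConfig(mcmc.n_iterations, mcmc.burn_in, mcmc.thin,
                               seed=mcmc.seed + 7919 * fold)
        post = run_sampler(genotypes.subset_individuals(
            [i for i in genotypes.individual_ids if i not in set(val_ids)]),
            train_tbl, trait, model, fold_mcmc)
        gebv = gebv_from_effects(genotypes.subset_individuals(val_ids),
                                 post.effect_means, post.centering_freqs)
        preds.update(gebv.to_dict())
    return reliability(pd.Series(preds), adjusted, scheme, f"bayes{model.family}", trait)


# ---------------------------------------------------------------------------
# Marker-density experiment


@dataclass
class DensityCurve:
    """Mean CV reliability per marker density over repeated random panels."""

    densities: list
    repeat_r2: dict = field(default_factory=dict)  # density -> list of mean_r2

    def mean_r2(self) -> pd.Series:
        return pd.Series({d: float(np.mean(v)) for d, v in self.repeat_r2.items()})

    def capability(self) -> pd.Series:
        """Mean reliability at each density relative to the largest density."""
        means = self.mean_r2()
        return means / means.loc[max(self.densities)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"density": d, "repeat": r, "mean_r2": v}
            for d in self.densities
            for r, v in enumerate(self.repeat_r2[d], start=1)
        ]
        return pd.DataFrame(rows)


PAPER_DENSITY_GRID_K = (0.5, 1, 3, 5, 10, 50, 100, 500)


def default_density_grid(n_markers: int, full_panel: int = 1_000_000) -> list:
    """The 0.5-500 K grid, scaled proportionally to a smaller panel and capped."""
    grid = sorted({max(1, min(n_markers, int(round(k * 1000 * n_markers / full_panel))))
                   for k in PAPER_DENSITY_GRID_K})
    if n_markers not in grid:
        grid.append(n_markers)
    return grid


def density_experiment(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    trait: str,
    densities=None,
    repeats: int = 30,
    seed: int = 0,
    k: int = 5,
    adjusted: pd.Series | None = None,
) -> DensityCurve:
    """Subsample markers, rebuild G, run fivefold GBLUP CV, over a density grid.

    Fold assignment and marker subsampling use independent seed streams so
    all repeats share the same folds (the repeat index varies only the
    marker panel).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    densities = list(densities) if densities is not None else default_density_grid(
        genotypes.n_markers)
    if max(densities) > genotypes.n_markers:
        raise ValueError("largest density exceeds the available markers")
    rng_folds = np.random.default_rng(seed)
    rng_sub = np.random.default_rng(seed + 2**20)
    pheno_geno = [i for i in phenotypes.df["id"]
                  if i in set(genotypes.individual_ids)
                  and not np.isnan(phenotypes.df.set_index("id")[trait].loc[i])]
    scheme = make_folds(pheno_geno, k=k, seed=int(rng_folds.integers(0, 2**31 - 1)))
    if adjusted is None:
        adjusted = adjusted_phenotype(phenotypes, trait)

    curve = DensityCurve(densities)
    for d in densities:
        vals = []
        for _ in range(repeats):
            sub = genio.subsample_markers(genotypes, d,
                                          seed=int(rng_sub.integers(0, 2**31 - 1)))
            res = cross_validate("gblup", phenotypes, trait, scheme,
                                 genotypes=sub, adjusted=adjusted)
            vals.append(res.mean_r2)
            if d == genotypes.n_markers:
                # the full panel is deterministic; no need to repeat
                vals = vals * repeats
                break
        curve.repeat_r2[d] = vals
    return curve
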