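"""Constrained and unconstrained ordination of assemblage data.

Redundancy analysis (RDA) is the constrained form of PCA: each (centered)
species column is regressed on the standardized predictors, a PCA of the
fitted values gives the constrained axes, and a PCA of the residuals gives
the unconstrained ones. Conditioning variables may be partialled out first
(partial RDA), which is the basis of variance partitioning: the *total*
effect of a focal variable is the constrained fraction of an RDA on it
alone, while its *unique* effect is the constrained fraction after
residualizing on the conditioners — both expressed as fractions of the
original total species variance.

Species data are centered but not standardized, matching the common
practice for relative abundance data; a Hellinger pre-transformation is
available as an option. Sample scores are weighted sums of species scores
(``site_scores = Y_centered @ species_scores``), the convention that makes
passive projection of fossil assemblages a plain matrix product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CoreStratigraphy


@dataclass
class OrdinationModel:
    kind: str  # {"PCA", "RDA", "partial-RDA"}
    species_scores: pd.DataFrame  # taxon x constrained (or principal) axis
    site_scores: pd.DataFrame  # sample x axis (weighted sums of species scores)
    constrained_fractions: np.ndarray
    unconstrained_fractions: np.ndarray
    conditioned_fraction: float
    total_variance: float
    column_means: pd.Series  # training centering, needed for projection
    conditioning_variables: list = field(default_factory=list)
    dropped_predictors: list = field(default_factory=list)

    @property
    def fractions_sum(self) -> float:
        return (
            float(self.constrained_fractions.sum())
            + float(self.unconstrained_fractions.sum())
            + self.conditioned_fraction
        )


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValueError(f"constant predictor {bad!r}")
    return (X - X.mean()) / sd


def _drop_collinear(X: np.ndarray, names: list, tol: float = 1e-8):
    """Keep a maximal independent predictor subset, in input order."""
    kept_idx, dropped = [], []
    basis = np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        candidate = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(candidate, tol=tol * max(X.shape)) > basis.shape[1]:
            basis = candidate
            kept_idx.append(j)
        else:
            dropped.append(name)
    if dropped:
        warnings.warn(f"collinear predictors dropped: {dropped}", stacklevel=3)
    return kept_idx, dropped


def _species_matrix(species: pd.DataFrame, hellinger: bool) -> pd.DataFrame:
    if not hellinger:
        return species.astype(float)
    rows = species.sum(axis=1)
    return np.sqrt(species.div(rows.where(rows > 0, 1.0), axis=0))


def rda(
    species: pd.DataFrame,
    env: pd.DataFrame | None,
    conditioners: pd.DataFrame | None = None,
    hellinger: bool = False,
) -> OrdinationModel:
    """Redundancy analysis (PCA when ``env`` is None).

    ``species``: sample x taxon abundances (centered internally);
    ``env``: sample x predictor matrix (standardized internally;
    exactly collinear columns dropped deterministically in input order);
    ``conditioners``: variables to partial out of both blocks first.
    """
    S = _species_matrix(species, hellinger)
    means = S.mean()
    Y = (S - means).to_numpy(dtype=float)
    total = float((Y**2).sum())
    if total == 0:
        raise ValueError("species matrix has no variance")

    conditioned = 0.0
    cond_names: list = []
    if conditioners is not None and conditioners.shape[1] > 0:
        Z = _standardize(conditioners).to_numpy(dtype=float)
        Z = np.column_stack([np.ones(len(Z)), Z])
        coefz, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        fitted_z = Z @ coefz
        Y = Y - fitted_z
        conditioned = float((fitted_z**2).sum()) / total
        cond_names = list(conditioners.columns)

    if env is None or env.shape[1] == 0:
        u, s, vt = np.linalg.svd(Y, full_matrices=False)
        fractions = s**2 / total
        axes = [f"PC{i + 1}" for i in range(len(s))]
        V = vt.T
        return OrdinationModel(
            kind="PCA",
            species_scores=pd.DataFrame(V, index=species.columns, columns=axes),
            site_scores=pd.DataFrame(Y @ V, index=species.index, columns=axes),
            constrained_fractions=np.array([]),
            unconstrained_fractions=fractions,
            conditioned_fraction=conditioned,
            total_variance=total,
            column_means=means,
            conditioning_variables=cond_names,
        )

    if len(species) <= env.shape[1]:
        raise ValueError("need more samples than predictors")
    Xs = _standardize(env)
    Xm = Xs.to_numpy(dtype=float)
    if conditioners is not None and conditioners.shape[1] > 0:
        coefx, *_ = np.linalg.lstsq(Z, Xm, rcond=None)
        Xm = Xm - Z @ coefx
    kept, dropped = _drop_collinear(Xm, list(env.columns))
    Xm = Xm[:, kept]

    coef, *_ = np.linalg.lstsq(Xm, Y, rcond=None)
    F = Xm @ coef
    R = Y - F
    rank = np.linalg.matrix_rank(Xm)
    uc, sc, vct = np.linalg.svd(F, full_matrices=False)
    sc, vct = sc[:rank], vct[:rank]
    ur, sr, vrt = np.linalg.svd(R, full_matrices=False)
    constrained = sc**2 / total
    unconstrained = sr**2 / total
    axes = [f"RDA{i + 1}" for i in range(len(sc))]
    V = vct.T
    return OrdinationModel(
        kind="partial-RDA" if cond_names else "RDA",
        species_scores=pd.DataFrame(V, index=species.columns, columns=axes),
        site_scores=pd.DataFrame(Y @ V, index=species.index, columns=axes),
        constrained_fractions=constrained,
        unconstrained_fractions=unconstrained,
        conditioned_fraction=conditioned,
        total_variance=total,
        column_means=means,
        conditioning_variables=cond_names,
        dropped_predictors=dropped,
    )


def pca_species(species: pd.DataFrame, hellinger: bool = False) -> OrdinationModel:
    """Unconstrained PCA of (centered) species data."""
    return rda(species, env=None, hellinger=hellinger)


def _constrained_ss(Y: np.ndarray, x: np.ndarray) -> float:
    """Sum of squares of Y explained by the single centered predictor x."""
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        return 0.0
    proj = xc @ Y  # 1 x m
    return float((proj**2).sum() / denom)


def permutation_significance(
    species: pd.DataFrame,
    env: pd.DataFrame,
    variables=None,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    hellinger: bool = False,
) -> pd.DataFrame:
    """Marginal permutation test of each environmental variable.

    For each variable, the statistic is the species variance constrained
    by that variable alone; the null distribution permutes the variable's
    values across samples. Returns a frame with the constrained fraction
    and the +1-corrected p-value per variable.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    variables = list(env.columns) if variables is None else list(variables)
    S = _species_matrix(species, hellinger)
    Y = (S - S.mean()).to_numpy(dtype=float)
    total = float((Y**2).sum())
    rows = []
    for v in variables:
        x = env[v].to_numpy(dtype=float)
        obs = _constrained_ss(Y, x)
        exceed = 0
        for _ in range(n_perm):
            if _constrained_ss(Y, rng.permutation(x)) >= obs:
                exceed += 1
        rows.append(
            {
                "variable": v,
                "constrained_fraction": obs / total,
                "p": (1 + exceed) / (n_perm + 1),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class VariancePartition:
    total_fraction: float
    unique_fraction: float
    focal: str
    conditioners: list


def variance_partition(
    species: pd.DataFrame,
    env: pd.DataFrame,
    focal: str,
    conditioners,
    hellinger: bool = False,
) -> VariancePartition:
    """Total and unique species variance attributable to one variable.

    ``total`` = constrained fraction of an RDA on the focal variable
    alone; ``unique`` = constrained fraction of a partial RDA on the focal
    after partialling out the conditioners, still expressed as a fraction
    of the *original* total species variance. A focal variable lying in
    the conditioners' span has unique fraction 0.
    """
    conditioners = list(conditioners)
    if focal in conditioners:
        raise ValueError("focal variable cannot be one of the conditioners")
    full = rda(species, env[[focal]], hellinger=hellinger)
    total_fraction = float(full.constrained_fractions.sum())
    S = _species_matrix(species, hellinger)
    Y = (S - S.mean()).to_numpy(dtype=float)
    total_ss = float((Y**2).sum())
    Z = _standardize(env[conditioners]).to_numpy(dtype=float)
    Z = np.column_stack([np.ones(len(Z)), Z])
    Yr = Y - Z @ np.linalg.lstsq(Z, Y, rcond=None)[0]
    x = env[focal].to_numpy(dtype=float)
    xr = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    if float(xr @ xr) < 1e-12 * max(float(x @ x), 1.0):
        warnings.warn(
            "focal variable lies in the conditioners' span; unique "
            "fraction is 0",
            stacklevel=2,
        )
        unique = 0.0
    else:
        unique = _constrained_ss(Yr, xr) / total_ss
    return VariancePartition(total_fraction, float(unique), focal, conditioners)


def passive_project(
    model: OrdinationModel, fossil: CoreStratigraphy | pd.DataFrame
) -> pd.DataFrame:
    """Project fossil assemblages onto a fitted ordination.

    Fossil taxa are intersected with the training taxa, the rows
    renormalized over the intersection, centered with the *training*
    column means, and multiplied by the training species scores. Rows come
    back in core (date) order, ready for trajectory plotting.
    """
    fossil_df = fossil.abundances if isinstance(fossil, CoreStratigraphy) else fossil
    common = fossil_df.columns.intersection(model.species_scores.index)
    if len(common) == 0:
        raise ValueError("fossil and training taxa do not intersect")
    sub = fossil_df[common]
    sums = sub.sum(axis=1)
    sub = sub.div(sums.where(sums > 0, 1.0), axis=0)
    centered = sub - model.column_means.reindex(common).fillna(0.0)
    scores = centered.to_numpy() @ model.species_scores.loc[common].to_numpy()
    return pd.DataFrame(
        scores, index=fossil_df.index, columns=model.species_scores.columns
    )
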