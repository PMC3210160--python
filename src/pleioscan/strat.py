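"""Covariate construction: age/sex residualisation and genotype PCA for
population-stratification correction.

The default workflow pre-adjusts phenotypes — each trait is replaced by
its least-squares residual on an intercept, age, sex and the top genotype
principal components — and the association scan then runs on the adjusted
traits with no further covariates.  Genotype PCA uses the standard
variance-stabilised scaling: each SNP column is centred at twice its
estimated allele frequency and divided by the binomial SD
``sqrt(2 p (1-p))``, so eigenvectors reflect ancestry rather than allele
frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.utils.extmath import randomized_svd

from .datatypes import GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class AdjustedPhenotypes:
    """Residualised traits plus the recipe that produced them."""

    data: pd.DataFrame  # sample_id + one column per adjusted trait
    recipe: dict


def _design_matrix(covs: pd.DataFrame, terms: list[str]) -> np.ndarray:
    missing = [t for t in terms if t not in covs.columns]
    if missing:
        raise ValueError(f"covariate columns not found: {missing}")
    X = np.column_stack([np.ones(len(covs))] + [covs[t].to_numpy(float) for t in terms])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear = [
            t for i, t in enumerate(terms)
            if np.linalg.matrix_rank(np.delete(X, i + 1, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return X


def residualize(
    y: np.ndarray | pd.Series, covs: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, dict]:
    """Least-squares residuals of ``y`` on intercept + selected covariates.

    Residuals are exactly orthogonal to every column of the design (up to
    numerical tolerance), so re-adjusting an adjusted trait is a no-op.
    Returns ``(residuals, recipe)``.
    """
    y = np.asarray(y, dtype=float)
    X = _design_matrix(covs, terms)
    if len(y) != X.shape[0]:
        raise ValueError("y and covariates disagree on sample count")
    if len(y) <= X.shape[1]:
        raise ValueError("need more samples than adjustment terms")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    recipe = {"terms": list(terms), "coefficients": beta.tolist(), "intercept_first": True}
    return resid, recipe


def adjust_traits(
    traits: pd.DataFrame,
    trait_cols: list[str],
    covs: pd.DataFrame | None = None,
    terms: list[str] | None = None,
) -> AdjustedPhenotypes:
    """Residualise each trait column on age/sex (+ optional PCs).

    ``covs`` defaults to the trait table itself (which carries age and
    sex); pass a merged frame to include principal components.  Rows with
    a missing trait value keep NaN in the output.
    """
    covs = traits if covs is None else covs
    terms = terms if terms is not None else ["age", "sex"]
    out = traits[["sample_id"]].copy()
    recipes = {}
    for col in trait_cols:
        y = traits[col].to_numpy(float)
        ok = ~np.isnan(y)
        resid = np.full_like(y, np.nan)
        resid[ok], recipes[col] = residualize(y[ok], covs.loc[ok], terms)
        out[col] = resid
    return AdjustedPhenotypes(data=out, recipe={"terms": terms, "per_trait": recipes})


def genotype_pca(
    G: GenotypeDataset, k: int = 10, scale: str = "eigenstrat", seed: int = 0
) -> pd.DataFrame:
    """Top-``k`` principal components of the genotype matrix.

    Missing dosages are mean-imputed per SNP; columns are centred at
    ``2 p_hat`` and, with the default scaling, divided by
    ``sqrt(2 p_hat (1 - p_hat))`` (``scale="cov"`` skips the division).
    Zero-variance SNPs are excluded with a log entry.  Returns a frame
    ``sample_id, pc_1 .. pc_k`` of unit-norm left singular vectors with
    the sign fixed so each component's largest-magnitude loading is
    positive.
    """
    if scale not in ("eigenstrat", "cov"):
        raise ValueError(f"unknown scaling: {scale!r}")
    if not 0 < k < min(G.n_samples, G.n_snps):
        raise ValueError("k must satisfy 0 < k < min(n_samples, n_snps)")

    X = G.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])

    p_hat = col_mean / 2.0
    keep = (p_hat > 0) & (p_hat < 1) & (np.nanstd(X, axis=0) > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("genotype_pca: excluded %d zero-variance SNPs", n_dropped)
    X = X[:, keep] - 2.0 * p_hat[keep]
    if scale == "eigenstrat":
        X /= np.sqrt(2.0 * p_hat[keep] * (1.0 - p_hat[keep]))

    U, s, _ = randomized_svd(X, n_components=k, n_iter=7, random_state=seed)
    # deterministic sign: largest-|loading| entry of each PC made positive
    for j in range(k):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]

    out = pd.DataFrame(U, columns=[f"pc_{j + 1}" for j in range(k)])
    out.insert(0, "sample_id", G.samples["sample_id"].to_numpy())
    return out
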