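"""Per-SNP association tests under the additive model.

The bivariate test treats each individual's phenotype as a length-2
vector ``y_i`` modelled as a grand mean plus covariate effects plus a
per-minor-allele SNP effect and correlated Gaussian error:

    y_i = mu + B_cov' z_i + beta_snp * x_i + eps_i,   eps_i ~ N2(0, Sigma)

The null restricts ``beta_snp = 0``.  Comparing residual
sum-of-squares-and-cross-products (SSCP) matrices under the two models
gives Wilks' lambda, ``L = |E| / |E + H|`` with ``E`` the full-model
residual SSCP and ``H`` the hypothesis SSCP; the likelihood ratio is a
monotone transform of ``L``.  For a single hypothesis degree of freedom
and two response variables the transformation

    F = ((1 - L) / L) * (nu_e - 1) / 2,   df = (2, nu_e - 1)

is *exactly* F-distributed under the null (nu_e = n - rank of the full
design), so the reported p-value is exact, not asymptotic.

Univariate tests are ordinary least-squares regressions of one trait on
the dosage (plus covariates) with a two-sided t-test on the slope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import GenotypeDataset


class MonomorphicError(ValueError):
    """SNP is constant among the analysed samples; no test possible."""


class DegenerateResidualError(ValueError):
    """Residual SSCP is singular (collinear traits or perfect fit)."""


@dataclass(frozen=True)
class BivariateFit:
    beta_snp: np.ndarray  # length-2 effect of one minor-allele copy
    E: np.ndarray  # 2x2 residual SSCP under the alternative
    H: np.ndarray  # 2x2 hypothesis SSCP
    wilks_lambda: float
    F: float
    df1: int
    df2: int
    p: float
    n: int


@dataclass(frozen=True)
class UnivariateFit:
    beta: float
    se: float
    t: float
    p: float
    n: int


def _complete_rows(
    y: np.ndarray, x: np.ndarray, Z: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    ok = ~np.isnan(x) & ~np.isnan(y).any(axis=1)
    if Z is not None:
        ok &= ~np.isnan(Z).any(axis=1)
        return y[ok], x[ok], Z[ok]
    return y[ok], x[ok], None


def fit_bivariate(
    y: np.ndarray, x: np.ndarray, Z: np.ndarray | None = None
) -> BivariateFit:
    """Exact Wilks-lambda F-test of a SNP's joint effect on two traits.

    Parameters
    ----------
    y
        ``(n, 2)`` phenotype matrix.
    x
        Length-``n`` dosage vector (0/1/2, NaN = missing); rows with any
        missing value are dropped listwise.
    Z
        Optional ``(n, q)`` covariate design (no intercept column; one is
        added internally).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must be an (n, 2) matrix")
    y, x, Z = _complete_rows(y, x, Z)
    n = len(x)

    X0 = np.ones((n, 1)) if Z is None else np.column_stack([np.ones(n), Z])
    X1 = np.column_stack([X0, x])
    rank1 = np.linalg.matrix_rank(X1)
    if n <= rank1 + 3:
        raise ValueError("too few complete samples for the bivariate fit")
    if np.ptp(x) == 0:
        raise MonomorphicError("monomorphic in analyzed samples")
    if rank1 == np.linalg.matrix_rank(X0):
        # dosage perfectly explained by covariates: no testable SNP effect
        raise MonomorphicError("dosage collinear with covariates")

    B1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    R1 = y - X1 @ B1
    E = R1.T @ R1
    B0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    R0 = y - X0 @ B0
    E0 = R0.T @ R0  # = E + H
    H = E0 - E

    det_E = float(np.linalg.det(E))
    det_E0 = float(np.linalg.det(E0))
    if det_E <= 0 or det_E0 <= 0:
        raise DegenerateResidualError("degenerate residual covariance")
    lam = min(det_E / det_E0, 1.0)

    nu_e = n - rank1
    F = (1.0 - lam) / lam * (nu_e - 1) / 2.0
    p = float(stats.f.sf(F, 2, nu_e - 1))
    return BivariateFit(
        beta_snp=B1[-1].copy(),
        E=E,
        H=H,
        wilks_lambda=lam,
        F=float(F),
        df1=2,
        df2=nu_e - 1,
        p=max(p, np.finfo(float).tiny),
        n=n,
    )


def fit_univariate(
    y: np.ndarray, x: np.ndarray, Z: np.ndarray | None = None
) -> UnivariateFit:
    """OLS slope of one trait on the dosage, two-sided t-test p-value."""
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    y2, x2, Z2 = _complete_rows(y[:, None].repeat(2, axis=1), x, Z)
    y, x, Z = y2[:, 0], x2, Z2
    n = len(x)
    X = np.column_stack([np.ones(n)] if Z is None else [np.ones(n), Z])
    X = np.column_stack([X, x])
    if n <= X.shape[1] + 1:
        raise ValueError("too few complete samples for the univariate fit")
    if np.ptp(x) == 0:
        raise MonomorphicError("monomorphic in analyzed samples")
    res = sm.OLS(y, X).fit()
    se = res.bse[-1]
    tss = float(np.sum((y - y.mean()) ** 2))
    if not np.isfinite(se) or se <= 0 or res.ssr <= 1e-12 * max(tss, 1.0):
        raise DegenerateResidualError("zero residual variance")
    return UnivariateFit(
        beta=float(res.params[-1]),
        se=float(se),
        t=float(res.tvalues[-1]),
        p=float(res.pvalues[-1]),
        n=n,
    )


def scan(
    G: GenotypeDataset,
    traits: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    covariates: pd.DataFrame | None = None,
    cov_terms: Sequence[str] = (),
) -> pd.DataFrame:
    """Genome-wide table of bivariate and univariate association results.

    For every SNP and every trait pair a Wilks-lambda F-test p-value; for
    every SNP and every single trait a univariate OLS p-value.  Traits are
    normally pre-adjusted (age, sex, PCs), in which case no covariates are
    passed here; a joint-covariate mode is available via ``covariates`` +
    ``cov_terms``.  SNPs failing preconditions keep their row with NaN
    p-values and a reason code.  Listwise deletion per SNP; the analysed
    sample count is recorded per row.
    """
    trait_names = sorted({t for pair in pairs for t in pair})
    for t in trait_names:
        if t not in traits.columns:
            raise ValueError(f"trait column missing: {t}")
    if not np.array_equal(
        G.samples["sample_id"].to_numpy(), traits["sample_id"].to_numpy()
    ):
        raise ValueError("genotype and trait tables disagree on samples")

    Z = None
    if cov_terms:
        if covariates is None:
            raise ValueError("cov_terms given without a covariate table")
        Z = covariates[list(cov_terms)].to_numpy(float)

    Y = {t: traits[t].to_numpy(float) for t in trait_names}
    mafs = G.maf()
    rows = []
    for j in range(G.n_snps):
        x = G.dosages[:, j]
        meta = G.snps.iloc[j]
        row: dict = {
            "snp_id": meta["snp_id"],
            "chrom": meta["chrom"],
            "pos": meta["pos"],
            "minor_allele": meta["minor_allele"],
            "major_allele": meta["major_allele"],
            "maf": mafs[j],
            "n_analyzed": int(np.sum(~np.isnan(x))),
            "reason": "",
        }
        try:
            for t1, t2 in pairs:
                fit = fit_bivariate(np.column_stack([Y[t1], Y[t2]]), x, Z)
                row[f"p_biv_{t1}_{t2}"] = fit.p
                row[f"beta_{t1}_{t2}_1"] = fit.beta_snp[0]
                row[f"beta_{t1}_{t2}_2"] = fit.beta_snp[1]
                row["n_analyzed"] = fit.n
            for t in trait_names:
                ufit = fit_univariate(Y[t], x, Z)
                row[f"p_uni_{t}"] = ufit.p
                row[f"beta_uni_{t}"] = ufit.beta
        except (MonomorphicError, DegenerateResidualError, ValueError) as err:
            row["reason"] = str(err)
        rows.append(row)

    out = pd.DataFrame(rows)
    return out


def threshold_view(
    results: pd.DataFrame, p_column: str, threshold: float
) -> pd.DataFrame:
    """Rows whose ``p_column`` is strictly below ``threshold``, sorted by p."""
    hits = results[results[p_column] < threshold]
    return hits.sort_values(p_column).reset_index(drop=True)


def bonferroni(results: pd.DataFrame, p_columns: Sequence[str]) -> pd.DataFrame:
    """Append Bonferroni-adjusted columns (an extension beyond the raw-p
    reporting convention; labelled ``*_bonf``)."""
    out = results.copy()
    m = len(results)
    for col in p_columns:
        out[f"{col}_bonf"] = np.minimum(out[col] * m, 1.0)
    return out
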