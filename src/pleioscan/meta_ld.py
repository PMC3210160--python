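"""Fisher's-method meta-analysis and pairwise linkage disequilibrium.

Fisher's combined probability test aggregates independent p-values from
k cohorts: ``X = -2 * sum(ln p_i)`` is chi-square distributed with 2k
degrees of freedom under the joint null, and the combined p-value is its
upper tail.

LD between two biallelic loci is characterised from unphased genotypes
by estimating the four two-locus haplotype frequencies with an EM
algorithm (the only ambiguous configuration is the double heterozygote,
whose two phasings are weighted by their current relative likelihood).
From the haplotype frequencies, ``D = p_AB - p_A p_B`` and the
standardised ``D' = |D| / D_max`` in [0, 1], with ``D_max`` the largest
magnitude D can attain given the allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeDataset


@dataclass(frozen=True)
class MetaResult:
    statistic: float  # -2 * sum(ln p)
    df: int  # 2k
    p_combined: float


@dataclass(frozen=True)
class LDResult:
    hap_freqs: np.ndarray  # (p_AB, p_Ab, p_aB, p_ab); A/B = minor alleles
    D: float
    Dmax: float
    dprime: float
    r2: float
    em_iterations: int
    loglik: float


def fisher_combine(pvals: Sequence[float]) -> MetaResult:
    """Combine k >= 2 independent p-values by Fisher's method."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size < 2:
        raise ValueError("need at least two p-values to combine")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    X = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return MetaResult(statistic=X, df=df, p_combined=float(stats.chi2.sf(X, df)))


def _genotype_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts; entry [i, j] = #samples with dosages i, j."""
    table = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            table[i, j] = np.sum((g1 == i) & (g2 == j))
    return table


def em_haplotype_freqs(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LDResult:
    """Two-locus haplotype frequencies from unphased dosages, via EM.

    ``g1``/``g2`` are 0/1/2 minor-allele dosage vectors (NaN = missing);
    only samples non-missing at both loci enter.  EM starts from
    linkage-equilibrium products and iterates until the log-likelihood
    change falls below ``tol`` or ``max_iter`` is reached; the log-likelihood
    is checked to be non-decreasing at every step.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    g1, g2 = g1[ok], g2[ok]
    n = len(g1)
    if n < 10:
        raise ValueError("need at least 10 samples non-missing at both loci")
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        raise ValueError("LD undefined: at least one locus is monomorphic")

    counts = _genotype_table(g1, g2)
    pA = g1.mean() / 2.0  # minor-allele frequency, locus 1
    pB = g2.mean() / 2.0
    # haplotypes ordered (AB, Ab, aB, ab); start at LE products
    h = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])

    def loglik_of(h: np.ndarray) -> float:
        ll = 0.0
        for i in range(3):
            for j in range(3):
                if counts[i, j] == 0:
                    continue
                prob = _genotype_prob(h, i, j)
                ll += counts[i, j] * np.log(max(prob, 1e-300))
        return ll

    n_dh = counts[1, 1]  # double heterozygotes: phase-ambiguous
    ll_prev = loglik_of(h)
    iters = 0
    for iters in range(1, max_iter + 1):
        # E-step: expected haplotype counts (2n haplotypes total)
        exp_counts = np.zeros(4)
        # unambiguous contributions: each genotype combo (i,j) other than
        # (1,1) implies fixed haplotype counts
        for i in range(3):
            for j in range(3):
                if (i, j) == (1, 1) or counts[i, j] == 0:
                    continue
                exp_counts += counts[i, j] * _unambiguous_haps(i, j)
        if n_dh > 0:
            w_cis = h[0] * h[3]
            w_trans = h[1] * h[2]
            tot = w_cis + w_trans
            f_cis = 0.5 if tot == 0 else w_cis / tot
            exp_counts[0] += n_dh * f_cis
            exp_counts[3] += n_dh * f_cis
            exp_counts[1] += n_dh * (1 - f_cis)
            exp_counts[2] += n_dh * (1 - f_cis)
        h_new = exp_counts / (2.0 * n)
        ll = loglik_of(h_new)
        if ll < ll_prev - 1e-8:
            raise RuntimeError("EM log-likelihood decreased; numerical failure")
        h, delta, ll_prev = h_new, ll - ll_prev, ll
        if abs(delta) < tol:
            break

    pA_hat = h[0] + h[1]
    pB_hat = h[0] + h[2]
    D = float(h[0] - pA_hat * pB_hat)
    if D >= 0:
        Dmax = min(pA_hat * (1 - pB_hat), (1 - pA_hat) * pB_hat)
    else:
        Dmax = min(pA_hat * pB_hat, (1 - pA_hat) * (1 - pB_hat))
    dprime = 0.0 if Dmax == 0 else abs(D) / Dmax
    denom = pA_hat * (1 - pA_hat) * pB_hat * (1 - pB_hat)
    r2 = 0.0 if denom == 0 else D * D / denom
    return LDResult(
        hap_freqs=h,
        D=D,
        Dmax=float(Dmax),
        dprime=float(min(dprime, 1.0)),
        r2=float(r2),
        em_iterations=iters,
        loglik=ll_prev,
    )


def _unambiguous_haps(i: int, j: int) -> np.ndarray:
    """Haplotype counts (AB, Ab, aB, ab) implied by dosages (i, j) != (1,1)."""
    # copies of A-at-locus-1 split across the two haplotypes; for any combo
    # with at most one het locus the phase is determined
    hap1 = (min(i, 1), min(j, 1))  # first haplotype carries the het allele
    hap2 = (i - hap1[0], j - hap1[1])
    out = np.zeros(4)
    for a, b in (hap1, hap2):
        out[(1 - a) * 2 + (1 - b)] += 1
    return out


def _genotype_prob(h: np.ndarray, i: int, j: int) -> float:
    """P(dosage pair (i, j)) under random union of haplotypes."""
    # haplotype k carries A iff k in (0,1); carries B iff k in (0,2)
    a_of = (1, 1, 0, 0)
    b_of = (1, 0, 1, 0)
    prob = 0.0
    for k in range(4):
        for l in range(4):
            if a_of[k] + a_of[l] == i and b_of[k] + b_of[l] == j:
                prob += h[k] * h[l]
    return prob


def region_ld_profile(
    G: GenotypeDataset,
    snp_ids: Sequence[str],
    assoc_p: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise D' matrix over a region plus an aligned association column.

    Returns ``(dprime, table)``: a symmetric D' DataFrame (diagonal 1 by
    convention) indexed by SNP id, and a per-SNP table with position and,
    when ``assoc_p`` (indexed by SNP id) is given, ``neg_log10_p``.
    """
    idx = [G.snp_index(s) for s in snp_ids]  # KeyError names unknown ids
    k = len(snp_ids)
    mat = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            res = em_haplotype_freqs(G.dosages[:, idx[a]], G.dosages[:, idx[b]])
            mat[a, b] = mat[b, a] = res.dprime
    dprime = pd.DataFrame(mat, index=list(snp_ids), columns=list(snp_ids))

    table = G.snps.iloc[idx][["snp_id", "chrom", "pos"]].reset_index(drop=True)
    if assoc_p is not None:
        table["p"] = [float(assoc_p[s]) for s in snp_ids]
        table["neg_log10_p"] = -np.log10(table["p"])
    return dprime, table


def plot_region(
    dprime: pd.DataFrame, table: pd.DataFrame, path: str
) -> None:  # pragma: no cover - optional plotting
    """Association track over a D' heatmap (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(8, 7), gridspec_kw={"height_ratios": [1, 1.4]}
    )
    if "neg_log10_p" in table.columns:
        ax0.scatter(table["pos"], table["neg_log10_p"], c="tab:blue")
        ax0.set_ylabel(r"$-\log_{10} p$")
    ax0.set_xlabel("position (bp)")
    im = ax1.imshow(dprime.to_numpy(), vmin=0, vmax=1, cmap="Reds")
    ax1.set_xticks(range(len(dprime)), dprime.columns, rotation=90, fontsize=6)
    ax1.set_yticks(range(len(dprime)), dprime.index, fontsize=6)
    fig.colorbar(im, ax=ax1, label="D'")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
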